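"""UMI-aware 3'-window quantification and stress-response scoring.

Reads are collapsed to molecules by their (chromosome, strand, 5' position,
UMI) identity, counted inside each gene's 3'-end window (400 bp upstream of
the 3' end to 200 bp downstream), and nonuniquely aligned molecules are
split between candidate loci in proportion to the unique-molecule counts of
those windows. Downstream scores summarize each gene's stress response as
the integrated log2 change over the time course (AUC) and rank genes by the
ratio of wild-type to double-deletion induction (dependency score).
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    EmptyInputError,
    ExpressionTimecourse,
    GenomeAnnotation,
    ParameterError,
)
from .synthetic import gene_quant_window

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# UMI collapse and gene quantification
# ---------------------------------------------------------------------------

def umi_collapse(alignments: pd.DataFrame) -> pd.DataFrame:
    """Unique-UMI counts per (chrom, strand, position).

    The count at a position is the number of distinct UMI strings among
    reads whose 5' position falls there (PCR duplicates collapse); it is
    bounded by 4^umi_length, the number of possible UMIs.
    """
    if alignments.empty:
        raise EmptyInputError("empty alignment table")
    lengths = alignments["umi"].str.len().unique()
    if len(lengths) != 1 or lengths[0] == 0:
        raise ParameterError("UMI strings must be non-empty with one fixed length")
    out = (
        alignments.groupby(["chrom", "strand", "pos"], as_index=False)["umi"]
        .nunique()
        .rename(columns={"umi": "count"})
    )
    cap = 4 ** int(lengths[0])
    out["count"] = out["count"].clip(upper=cap)
    return out


def _windows(annotation: GenomeAnnotation) -> pd.DataFrame:
    rows = []
    for _, r in annotation.genes.iterrows():
        start, end = gene_quant_window(r, annotation.chrom_lengths.get(r["chrom"]))
        rows.append((r["gene"], r["chrom"], start, end))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _genes_at(windows: pd.DataFrame, chrom: str, pos: int) -> list[str]:
    w = windows[(windows["chrom"] == chrom) & (windows["start"] <= pos) & (pos < windows["end"])]
    return w["gene"].tolist()


def quantify_genes(
    alignments: pd.DataFrame,
    annotation: GenomeAnnotation,
    max_alignments: int = 2,
) -> pd.Series:
    """Per-gene molecule counts with UMI collapse and multimapper splitting.

    Uniquely aligned reads are collapsed to molecules by (chrom, strand,
    position, UMI); a unique molecule inside one gene window counts 1 (a
    molecule in k overlapping windows is split by the same unique-ratio
    rule, and the overlap is logged). Multimapped reads are grouped into
    molecules by (UMI, set of loci); each contributes u_g / sum(u) to
    candidate gene g, where u are the unique-molecule counts of the
    candidate windows, or 1/k when all u are zero. Assigned mass is
    conserved. Upstream alignment is expected to cap reported loci at 2; a
    higher n_alignments only triggers a warning.
    """
    if alignments.empty:
        raise EmptyInputError("empty alignment table")
    if (alignments["n_alignments"] > max_alignments).any():
        warnings.warn(f"reads with more than {max_alignments} alignments present")
    windows = _windows(annotation)
    overlap = _log_window_overlaps(windows)
    counts = pd.Series(0.0, index=annotation.genes["gene"].tolist())

    uniq = alignments[alignments["n_alignments"] == 1]
    multi = alignments[alignments["n_alignments"] > 1]

    # unique molecules per window (the splitting weights)
    u_mol = uniq.drop_duplicates(["chrom", "strand", "pos", "umi"])
    u_counts = {g: 0.0 for g in counts.index}
    assignments = []  # (genes, ) per unique molecule
    for _, m in u_mol.iterrows():
        hits = _genes_at(windows, m["chrom"], m["pos"])
        assignments.append(hits)
        for g in hits:
            u_counts[g] += 1.0
    for hits in assignments:
        if not hits:
            continue
        if len(hits) == 1:
            counts[hits[0]] += 1.0
        else:  # overlapping windows: split by unique-count ratio
            u = np.array([u_counts[g] for g in hits])
            share = u / u.sum() if u.sum() > 0 else np.full(len(hits), 1.0 / len(hits))
            for g, s in zip(hits, share):
                counts[g] += s

    if not multi.empty:
        # molecules keyed by UMI + the full set of aligned loci
        loci = (
            multi.assign(locus=list(zip(multi["chrom"], multi["pos"])))
            .groupby(["read_id", "umi"])["locus"]
            .apply(lambda s: tuple(sorted(s)))
            .reset_index()
        )
        molecules = loci.drop_duplicates(["umi", "locus"])
        for _, m in molecules.iterrows():
            cand: list[str] = []
            for chrom, pos in m["locus"]:
                for g in _genes_at(windows, chrom, pos):
                    if g not in cand:
                        cand.append(g)
            if not cand:
                continue
            u = np.array([u_counts[g] for g in cand])
            share = u / u.sum() if u.sum() > 0 else np.full(len(cand), 1.0 / len(cand))
            for g, s in zip(cand, share):
                counts[g] += s
    if overlap:
        log.info("quantified with %d overlapping window pairs (mass split)", overlap)
    return counts


def _log_window_overlaps(windows: pd.DataFrame) -> int:
    n = 0
    for chrom, grp in windows.groupby("chrom"):
        w = grp.sort_values("start")
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        n += int(np.sum(starts[1:] < ends[:-1]))
    return n


# ---------------------------------------------------------------------------
# Time-course assembly and QC
# ---------------------------------------------------------------------------

def build_timecourse(
    counts: pd.DataFrame,
    raw_totals: pd.Series,
    min_reads: int = 150_000,
    strain: str = "",
    condition: str = "",
) -> ExpressionTimecourse:
    """Normalize samples to 1e6 reads and patch low-coverage timepoints.

    ``counts`` is genes x timepoints (minutes); ``raw_totals`` gives each
    sample's raw aligned-read total. Samples under ``min_reads`` are
    discarded (they would artificially enrich for highly expressed genes):
    an interior discarded timepoint is replaced by the mean of the nearest
    retained earlier and later samples, a boundary one by the single nearest
    retained sample.
    """
    if counts.shape[1] < 3:
        raise ParameterError("need >= 3 samples per time course")
    times = list(counts.columns)
    raw_totals = raw_totals.reindex(times)
    kept = [t for t in times if raw_totals[t] >= min_reads]
    if not kept:
        raise ParameterError("all samples fall below the read threshold")
    discarded = [t for t in times if t not in kept]

    norm = counts.astype(float).copy()
    for t in kept:
        s = norm[t].sum()
        if s <= 0:
            raise ParameterError(f"sample {t} has zero counts")
        norm[t] = norm[t] * (1e6 / s)
    for t in discarded:
        earlier = [u for u in kept if u < t]
        later = [u for u in kept if u > t]
        if earlier and later:
            norm[t] = 0.5 * (norm[earlier[-1]] + norm[later[0]])
        elif earlier:
            norm[t] = norm[earlier[-1]]
        else:
            norm[t] = norm[later[0]]
    return ExpressionTimecourse(
        values=norm, raw_totals=raw_totals, discarded=discarded,
        strain=strain, condition=condition,
    )


# ---------------------------------------------------------------------------
# Response scoring
# ---------------------------------------------------------------------------

def response_auc(tc: ExpressionTimecourse, pseudocount: float = 1.0) -> pd.Series:
    """Integrated log2 change over the time course (trapezoid; log2*min).

    auc_g = integral over t of log2((x_g(t) + p) / (x_g(0) + p)); the
    pre-stress timepoint 0 is the reference, so an unchanged gene scores 0.
    """
    times = np.asarray(tc.values.columns, dtype=float)
    if times[0] != 0:
        raise ParameterError("timepoint 0 (pre-stress reference) required")
    x = tc.values.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ParameterError("negative expression values")
    ref = x[:, [0]]
    lfc = np.log2((x + pseudocount) / (ref + pseudocount))
    auc = np.trapezoid(lfc, times, axis=1)
    return pd.Series(auc, index=tc.values.index, name="auc")


def peak_induction(tc: ExpressionTimecourse, pseudocount: float = 1.0) -> pd.Series:
    """Alternative induction summary: max log2 fold change over the course."""
    times = np.asarray(tc.values.columns, dtype=float)
    if times[0] != 0:
        raise ParameterError("timepoint 0 (pre-stress reference) required")
    x = tc.values.to_numpy(dtype=float)
    lfc = np.log2((x + pseudocount) / (x[:, [0]] + pseudocount))
    return pd.Series(lfc.max(axis=1), index=tc.values.index, name="peak")


def dependency_score(
    auc_by_strain: dict,
    wt: str = "WT",
    double: str = "msn2msn4",
    eps: float = 1.0,
) -> pd.DataFrame:
    """Rank genes by mean WT / double-deletion induction ratio.

    ``auc_by_strain`` maps strain name -> genes x conditions AUC frame. The
    score for a gene is the mean over conditions of
    (WT auc + eps) / (double auc + eps); genes are returned sorted by
    descending score. The regularizer eps tames near-zero denominators.
    """
    missing = [s for s in (wt, double) if s not in auc_by_strain]
    if missing:
        raise ParameterError(f"missing strains: {missing}")
    a_wt = auc_by_strain[wt]
    a_dd = auc_by_strain[double]
    if list(a_wt.columns) != list(a_dd.columns):
        raise ParameterError("WT and double-deletion AUCs must share conditions")
    ratio = (a_wt + eps) / (a_dd + eps)
    out = pd.DataFrame({"dependency": ratio.mean(axis=1)})
    out = out.sort_values("dependency", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_targets(
    auc_by_strain: dict,
    condition,
    fold: float = 2.0,
    wt: str = "WT",
    double: str = "msn2msn4",
) -> pd.Series:
    """Boolean target call: WT induction strictly > fold x double-deletion."""
    missing = [s for s in (wt, double) if s not in auc_by_strain]
    if missing:
        raise ParameterError(f"missing strains: {missing}")
    a_wt = auc_by_strain[wt][condition]
    a_dd = auc_by_strain[double][condition]
    return (a_wt > fold * a_dd).rename("is_target")


# ---------------------------------------------------------------------------
# Expression variability / flexibility
# ---------------------------------------------------------------------------

def expression_variability(
    datasets: dict,
    gene: str,
    min_samples: int = 20,
    log2: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Across-sample variance of one gene's expression, per data set.

    Data sets with fewer than ``min_samples`` samples (the minimum for a
    meaningful variance comparison) are skipped with a warning.
    """
    rows = []
    for name, df in datasets.items():
        if df.shape[1] < min_samples:
            warnings.warn(f"data set {name!r} has <{min_samples} samples; skipped")
            continue
        x = df.loc[gene].to_numpy(dtype=float)
        if log2:
            x = np.log2(x + pseudocount)
        rows.append({"dataset": name, "n_samples": df.shape[1], "variance": float(np.var(x, ddof=1))})
    return pd.DataFrame(rows)


def max_fold_change(expression: pd.Series) -> float:
    """Flexibility of a gene: max/min expression across a condition panel."""
    x = expression.to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ParameterError("fold change requires strictly positive expression")
    return float(x.max() / x.min())
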