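"""Binding-signal tracks and sequence preference from read 5' ends.

The first nucleotide of every aligned read is counted as binding signal and
the genome-wide track is normalized to a fixed total (1e7 for cleavage
data; the same operation builds 5'-end mRNA tracks with another constant).
Promoters are the 700 bp upstream of each TSS, truncated at the nearest
upstream transcript. Sequence preference is scored per 7-mer as the mean
signal in a +/-10 bp window around each promoter occurrence, z-scored
across k-mers; the TATA scanner matches the consensus TATA[AT]A[AT].
"""
from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datatypes import EmptyInputError, GenomeAnnotation, ParameterError

_RC = str.maketrans("ACGTN", "TGCAN")

TATA_PATTERN = "TATA[AT]A[AT]"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def build_signal_track(
    alignments: pd.DataFrame,
    chrom_lengths: dict,
    total: float = 1e7,
    stranded: bool = False,
) -> dict:
    """Per-position read-start counts scaled to a fixed genome-wide total.

    Returns chrom -> float array (or (chrom, strand) -> array when
    ``stranded``). Only relative frequencies matter; scaling to ``total``
    conserves them exactly.
    """
    if alignments.empty:
        raise EmptyInputError("empty alignment table")
    keys: dict = {}
    if stranded:
        for (chrom, strand), grp in alignments.groupby(["chrom", "strand"]):
            arr = np.bincount(grp["pos"], minlength=chrom_lengths[chrom]).astype(float)
            keys[(chrom, strand)] = arr
    else:
        for chrom, grp in alignments.groupby("chrom"):
            keys[chrom] = np.bincount(grp["pos"], minlength=chrom_lengths[chrom]).astype(float)
    grand = sum(a.sum() for a in keys.values())
    scale = total / grand
    return {k: a * scale for k, a in keys.items()}


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def define_promoters(annotation: GenomeAnnotation, max_len: int = 700) -> pd.DataFrame:
    """Upstream promoter intervals: min(700 bp, gap to the upstream transcript).

    Strand-aware: on '+' the promoter is [TSS - L, TSS); on '-' it is
    (TSS, TSS + L] in 0-based half-open form. The gap to the nearest
    transcript body on either strand truncates L; intervals are clipped to
    chromosome bounds and zero-length promoters are flagged.
    """
    genes = annotation.genes
    bodies = []  # inclusive transcript bodies [lo, hi]
    for _, r in genes.iterrows():
        lo, hi = sorted((int(r["tss"]), int(r["end3"])))
        bodies.append((r["chrom"], lo, hi))

    rows = []
    for _, r in genes.iterrows():
        chrom, tss = r["chrom"], int(r["tss"])
        mylo, myhi = sorted((tss, int(r["end3"])))
        if r["strand"] == "+":
            gap = tss  # distance to the chromosome start by default
            for c, lo, hi in bodies:
                if c == chrom and (lo, hi) != (mylo, myhi) and hi < tss:
                    gap = min(gap, tss - hi - 1)
            L = min(max_len, gap)
            start, end = tss - L, tss
        else:
            clen = annotation.chrom_lengths.get(chrom)
            gap = (clen - tss - 1) if clen is not None else max_len
            for c, lo, hi in bodies:
                if c == chrom and (lo, hi) != (mylo, myhi) and lo > tss:
                    gap = min(gap, lo - tss - 1)
            L = min(max_len, gap)
            start, end = tss + 1, tss + 1 + L
        start = max(start, 0)
        clen = annotation.chrom_lengths.get(chrom)
        if clen is not None:
            end = min(end, clen)
        rows.append(
            {
                "gene": r["gene"], "chrom": chrom, "strand": r["strand"],
                "start": int(start), "end": int(end), "length": int(end - start),
                "truncated": bool(L < max_len), "empty": bool(end <= start),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Promoter binding scores
# ---------------------------------------------------------------------------

def promoter_binding(
    tracks: dict | list[dict], promoters: pd.DataFrame
) -> pd.DataFrame:
    """Per-promoter signal sums and z-scores; replicates reduced by median.

    ``tracks`` is one track (chrom -> array) or a list of replicate tracks.
    With replicates, per-promoter sums are computed per replicate, the
    median across replicates is taken, and the z-score is over promoters.
    """
    if promoters.empty:
        raise ParameterError("need >= 1 promoter")
    reps = tracks if isinstance(tracks, list) else [tracks]

    def _sums(track: dict) -> np.ndarray:
        out = np.zeros(len(promoters))
        for i, (_, p) in enumerate(promoters.iterrows()):
            if p["end"] > p["start"]:
                out[i] = track[p["chrom"]][p["start"] : p["end"]].sum()
        return out

    per_rep = np.vstack([_sums(t) for t in reps])
    med = np.median(per_rep, axis=0)
    sd = med.std(ddof=1) if len(med) > 1 else 0.0
    if sd == 0:
        # every promoter equals the mean; report zero deviation but warn
        warnings.warn("zero variance across promoters; z-scores degenerate")
        z = np.zeros(len(med))
    else:
        z = (med - med.mean()) / sd
    return pd.DataFrame(
        {"gene": promoters["gene"].to_numpy(), "signal": med, "z": z}
    ).set_index("gene")


def promoter_correlation(bindingA: pd.DataFrame, bindingB: pd.DataFrame) -> float:
    """Pearson correlation of two factors' per-promoter signal vectors."""
    joined = bindingA[["signal"]].join(bindingB[["signal"]], lsuffix="_A", rsuffix="_B")
    return float(pearsonr(joined["signal_A"], joined["signal_B"])[0])


# ---------------------------------------------------------------------------
# k-mer preference
# ---------------------------------------------------------------------------

def kmer_preference(
    track: dict,
    promoters: pd.DataFrame,
    genome: dict,
    k: int = 7,
    flank: int = 10,
    min_occurrences: int = 5,
    collapse_rc: bool = False,
) -> pd.DataFrame:
    """Mean windowed signal per k-mer across all promoter occurrences.

    For every k-mer occurrence inside a promoter, the track is summed over
    [occurrence_start - flank, occurrence_start + k + flank), clipped at the
    promoter edges, and averaged across occurrences. Both strands are
    scanned: each position contributes to the forward k-mer and, as a
    separate species, to its reverse complement. ``collapse_rc`` folds a
    k-mer and its reverse complement into one canonical species (the
    4^k / 2 = 8,192 convention for k = 7). z-scores are computed across
    k-mers observed at least ``min_occurrences`` times.
    """
    sums: dict = {}
    occs: dict = {}
    any_seq = False
    for _, p in promoters.iterrows():
        if p["end"] <= p["start"]:
            continue
        chrom, s, e = p["chrom"], int(p["start"]), int(p["end"])
        seq = genome[chrom][s:e].upper()
        if len(seq) < k:
            continue
        any_seq = True
        arr = track[chrom]
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            lo = max(s + i - flank, s)
            hi = min(s + i + k + flank, e)
            sig = float(arr[lo:hi].sum())
            rc = reverse_complement(km)
            species = {min(km, rc)} if collapse_rc else {km, rc}
            for sp in species:
                sums[sp] = sums.get(sp, 0.0) + sig
                occs[sp] = occs.get(sp, 0) + 1
    if not any_seq:
        raise ParameterError("no promoter sequence available")

    table = pd.DataFrame(
        {
            "kmer": list(sums),
            "n_occurrences": [occs[km] for km in sums],
            "mean_signal": [sums[km] / occs[km] for km in sums],
        }
    ).set_index("kmer")
    scored = table[table["n_occurrences"] >= min_occurrences]
    mu = scored["mean_signal"].mean()
    sd = scored["mean_signal"].std(ddof=1)
    table["z"] = np.nan
    if sd > 0:
        table.loc[scored.index, "z"] = (scored["mean_signal"] - mu) / sd
    elif not scored.empty:  # all means equal (e.g. a uniform track)
        table.loc[scored.index, "z"] = 0.0
    return table.sort_values("z", ascending=False)


def top_kmer(preference: pd.DataFrame) -> str:
    """The k-mer with the maximal z-score (the factor's preferred motif)."""
    scored = preference.dropna(subset=["z"])
    if scored.empty:
        raise EmptyInputError("no k-mer passed the occurrence threshold")
    return str(scored["z"].idxmax())


# ---------------------------------------------------------------------------
# TATA scanning
# ---------------------------------------------------------------------------

def scan_tata(genome: dict, promoters: pd.DataFrame) -> pd.DataFrame:
    """All TATA[AT]A[AT] matches within each promoter, both strands.

    Positions are 0-based genomic coordinates of the match's leftmost base
    on the forward strand. 'N' never matches.
    """
    fwd = re.compile(TATA_PATTERN)
    rows = []
    for _, p in promoters.iterrows():
        if p["end"] <= p["start"]:
            continue
        chrom, s, e = p["chrom"], int(p["start"]), int(p["end"])
        seq = genome[chrom][s:e].upper()
        for m in fwd.finditer(seq):
            rows.append({"gene": p["gene"], "chrom": chrom, "pos": s + m.start(), "strand": "+"})
        rc = reverse_complement(seq)
        L = len(seq)
        for m in fwd.finditer(rc):
            # map a match on the reverse strand back to forward coordinates
            rows.append(
                {"gene": p["gene"], "chrom": chrom,
                 "pos": s + L - m.start() - len(m.group(0)), "strand": "-"}
            )
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])
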