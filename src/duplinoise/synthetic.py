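"""Seeded generators for every input the analysis stages consume.

Each generator returns its dataset together with a :class:`GroundTruth`
record holding the true generative parameters, so recovery tests can compare
measured statistics against analytically expected values. All randomness
flows from one ``numpy.random.Generator`` per call; identical seeds and
parameters yield identical outputs.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (
    ALIGNMENT_COLUMNS,
    CellRecord,
    CountVector,
    EventTable,
    GenomeAnnotation,
    GroundTruth,
    GrowthCurve,
    ImageStack,
    ParameterError,
    TraceSet,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# mRNA counts
# ---------------------------------------------------------------------------

def simulate_mrna_counts(
    n_cells: int,
    model: str,
    seed: int,
    *,
    lam: float | None = None,
    burst_rate: float | None = None,
    burst_size: float | None = None,
    gene: str = "GENE",
    condition: str = "",
) -> tuple[CountVector, GroundTruth]:
    """Draw per-cell transcript counts from a Poisson or bursty law.

    The bursty model is the geometric-burst (negative-binomial) stationary
    law, drawn as a Gamma-Poisson mixture: mean = burst_rate * burst_size,
    Fano factor = 1 + burst_size.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    if model == "poisson":
        if lam is None or lam <= 0:
            raise ParameterError("poisson model requires lambda > 0")
        counts = rng.poisson(lam, size=n_cells)
        params = {"model": "poisson", "lambda": float(lam), "mean": float(lam), "fano": 1.0}
    elif model == "bursty":
        if burst_rate is None or burst_rate <= 0 or burst_size is None or burst_size <= 0:
            raise ParameterError("bursty model requires burst_rate > 0 and burst_size > 0")
        intensity = rng.gamma(shape=burst_rate, scale=burst_size, size=n_cells)
        counts = rng.poisson(intensity)
        params = {
            "model": "bursty",
            "burst_rate": float(burst_rate),
            "burst_size": float(burst_size),
            "mean": float(burst_rate * burst_size),
            "fano": float(1.0 + burst_size),
        }
    else:
        raise ParameterError(f"unknown count model {model!r}")
    cv = CountVector(counts=counts, gene=gene, condition=condition)
    return cv, GroundTruth(label=f"mrna_counts:{model}", params=params, seed=seed)


def simulate_telegraph_counts(
    n_cells: int,
    k_on: float,
    k_off: float,
    k_syn: float,
    k_deg: float = 1.0,
    t_end: float = 50.0,
    seed: int = 0,
) -> np.ndarray:
    """Brute-force Gillespie simulation of the two-state telegraph promoter.

    Slow; kept as an independent oracle for the negative-binomial burst law
    in the fast-switching (k_off >> k_on, k_syn >> k_off) limit, where the
    stationary counts approach NB with burst rate k_on/k_deg and burst size
    k_syn/k_off.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_cells, dtype=np.int64)
    for i in range(n_cells):
        t, state, m = 0.0, 0, 0
        while t < t_end:
            rates = np.array(
                [k_on if state == 0 else 0.0,
                 k_off if state == 1 else 0.0,
                 k_syn if state == 1 else 0.0,
                 k_deg * m]
            )
            total = rates.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= t_end:
                break
            ev = rng.choice(4, p=rates / total)
            if ev == 0:
                state = 1
            elif ev == 1:
                state = 0
            elif ev == 2:
                m += 1
            else:
                m -= 1
        out[i] = m
    return out


# ---------------------------------------------------------------------------
# Nuclear-localization traces and rendered movies
# ---------------------------------------------------------------------------

def simulate_localization_traces(
    n_cells: int,
    n_frames: int,
    shared_pulses: bool,
    pulse_rate: float = 0.05,
    pulse_amplitude: float = 3.0,
    noise_sd: float = 0.1,
    pulse_width: int = 5,
    seed: int = 0,
    channels: tuple[str, str] = ("GFP", "mCherry"),
) -> tuple[TraceSet, GroundTruth]:
    """Two-channel nuclear-localization ratio traces with stochastic pulses.

    Baseline ratio is 1; during a pulse the ratio steps to ``pulse_amplitude``
    (a fold increase) for ``pulse_width`` frames. With ``shared_pulses`` both
    channels of a cell pulse at identical frames, emulating two reporters
    driven by one upstream signal; otherwise pulse times are independent.
    """
    if n_frames < 10:
        raise ParameterError("n_frames must be >= 10")
    if pulse_amplitude <= 1:
        raise ParameterError("pulse_amplitude must exceed 1 (fold over baseline)")
    if not 0 <= pulse_rate <= 1:
        raise ParameterError("pulse_rate is a per-frame probability")
    rng = np.random.default_rng(seed)

    def _pulse_train() -> tuple[np.ndarray, list]:
        starts = np.flatnonzero(rng.random(n_frames) < pulse_rate)
        trace = np.ones(n_frames)
        for s in starts:
            trace[s : s + pulse_width] = pulse_amplitude
        return trace, starts.tolist()

    raw = {c: np.empty((n_cells, n_frames)) for c in channels}
    pulse_times: dict = {c: [] for c in channels}
    for i in range(n_cells):
        if shared_pulses:
            base, starts = _pulse_train()
            per_channel = {c: (base.copy(), starts) for c in channels}
        else:
            per_channel = {c: _pulse_train() for c in channels}
        for c in channels:
            trace, starts = per_channel[c]
            raw[c][i] = trace + rng.normal(0.0, noise_sd, size=n_frames)
            pulse_times[c].append(starts)

    ts = TraceSet(raw=raw, cell_ids=np.arange(n_cells))
    gt = GroundTruth(
        label="localization_traces",
        params={
            "shared_pulses": shared_pulses,
            "pulse_rate": pulse_rate,
            "pulse_amplitude": pulse_amplitude,
            "pulse_width": pulse_width,
            "noise_sd": noise_sd,
            "pulse_times": pulse_times,
        },
        seed=seed,
    )
    return ts, gt


def render_trace_movie(
    traces: TraceSet,
    cell_radius_px: int = 12,
    nucleus_radius_px: int = 3,
    image_shape: tuple[int, int] = (128, 128),
    psf_sd: float = 0.5,
    background: float = 10.0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    missing_frames: tuple = (),
    seed: int = 0,
) -> tuple[dict, np.ndarray, list, GroundTruth]:
    """Render traces into synthetic fluorescence movies with known masks.

    Cells are non-overlapping disks with a concentric nucleus; at each frame
    nuclear pixels carry ``baseline * trace_value`` while cytoplasm carries
    ``baseline``, then a Gaussian point-spread blur and additive noise are
    applied. Returns (stacks per channel, label mask image, cell records,
    ground truth). Frames listed in ``missing_frames`` are zeroed and flagged.
    """
    if nucleus_radius_px >= cell_radius_px:
        raise ParameterError("nucleus radius must be smaller than the cell radius")
    H, W = image_shape
    n_cells, n_frames = traces.n_cells, traces.n_frames
    pitch = 2 * cell_radius_px + 6
    cols = max((W - 2) // pitch, 0)
    rows = max((H - 2) // pitch, 0)
    if n_cells > rows * cols:
        raise ParameterError(
            f"cannot place {n_cells} cells of radius {cell_radius_px} in {image_shape}"
        )
    rng = np.random.default_rng(seed)
    centers = []
    for idx in range(n_cells):
        r, c = divmod(idx, cols)
        centers.append((1 + r * pitch + cell_radius_px, 1 + c * pitch + cell_radius_px))

    yy, xx = np.mgrid[0:H, 0:W]
    labels = np.zeros((H, W), dtype=np.int32)
    cell_masks, nuc_masks = [], []
    for i, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cmask = d2 <= cell_radius_px**2
        nmask = d2 <= nucleus_radius_px**2
        labels[cmask] = i + 1
        cell_masks.append(cmask)
        nuc_masks.append(nmask)

    missing = frozenset(int(i) for i in missing_frames)
    stacks = {}
    for ch in traces.channels:
        movie = np.empty((n_frames, H, W))
        for t in range(n_frames):
            frame = np.full((H, W), background, dtype=float)
            for i in range(n_cells):
                frame[cell_masks[i]] = baseline
                frame[nuc_masks[i]] = baseline * traces.raw[ch][i, t]
            if psf_sd > 0:
                frame = ndimage.gaussian_filter(frame, psf_sd)
            if noise_sd > 0:
                frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
            movie[t] = frame
        movie[list(missing)] = 0.0
        stacks[ch] = ImageStack(frames={ch: movie}, missing_frames=missing)

    cells = [
        CellRecord(
            cell_id=i + 1,
            mask=cell_masks[i],
            area=np.full(n_frames, cell_masks[i].sum(), dtype=float),
            seg_score=np.full(n_frames, 10.0),
        )
        for i in range(n_cells)
    ]
    gt = GroundTruth(
        label="trace_movie",
        params={
            "centers": centers,
            "cell_radius_px": cell_radius_px,
            "nucleus_radius_px": nucleus_radius_px,
            "baseline": baseline,
            "background": background,
            "psf_sd": psf_sd,
            "noise_sd": noise_sd,
            "missing_frames": sorted(missing),
        },
        seed=seed,
    )
    return stacks, labels, cells, gt


# ---------------------------------------------------------------------------
# UMI-tagged alignments over a toy genome
# ---------------------------------------------------------------------------

def gene_quant_window(row: pd.Series, chrom_length: int | None = None,
                      upstream: int = 400, downstream: int = 200) -> tuple[int, int]:
    """3'-end quantification window, 0-based half-open, strand-aware.

    On '+': [end3 - upstream, end3 + downstream); on '-' the mirrored
    interval [end3 - downstream + 1, end3 + upstream + 1). Clipped to the
    chromosome bounds when the length is known.
    """
    if row["strand"] == "+":
        start, end = row["end3"] - upstream, row["end3"] + downstream
    else:
        start, end = row["end3"] - downstream + 1, row["end3"] + upstream + 1
    start = max(int(start), 0)
    if chrom_length is not None:
        end = min(int(end), int(chrom_length))
    return start, int(end)


def simulate_umi_alignments(
    annotation: GenomeAnnotation,
    gene_expression: dict,
    umi_length: int = 8,
    multimap_fraction: float = 0.0,
    duplication: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """UMI-tagged read alignments with controlled PCR duplication/multimapping.

    Each gene receives exactly ``gene_expression[gene]`` distinct molecules,
    placed uniformly in its 3' quantification window with distinct
    (position, UMI) pairs. Every molecule is emitted ``duplication`` times
    (PCR duplicates share position and UMI). A ``multimap_fraction`` of
    molecules gains a second alignment locus in another gene's window; those
    reads appear once per locus with n_alignments = 2.
    """
    if not 0 <= multimap_fraction < 1:
        raise ParameterError("multimap_fraction must be in [0, 1)")
    if umi_length < 4:
        raise ParameterError("umi_length must be >= 4")
    if duplication < 1:
        raise ParameterError("duplication must be >= 1")
    rng = np.random.default_rng(seed)
    genes = annotation.genes.set_index("gene")
    for g in gene_expression:
        if g not in genes.index:
            raise KeyError(g)
    gene_names = list(genes.index)

    rows = []
    true_counts = {}
    read_counter = itertools.count()
    n_multi = 0
    for g, n_mol in gene_expression.items():
        n_mol = int(n_mol)
        true_counts[g] = n_mol
        if n_mol == 0:
            continue
        row = genes.loc[g]
        start, end = gene_quant_window(row, annotation.chrom_lengths.get(row["chrom"]))
        seen: set = set()
        for _ in range(n_mol):
            while True:
                pos = int(rng.integers(start, end))
                umi = "".join(rng.choice(_BASES, size=umi_length))
                if (pos, umi) not in seen:
                    seen.add((pos, umi))
                    break
            multi = rng.random() < multimap_fraction
            alt = None
            if multi and len(gene_names) > 1:
                other = gene_names[int(rng.integers(len(gene_names)))]
                while other == g:
                    other = gene_names[int(rng.integers(len(gene_names)))]
                orow = genes.loc[other]
                ostart, oend = gene_quant_window(orow, annotation.chrom_lengths.get(orow["chrom"]))
                alt = (orow["chrom"], int(rng.integers(ostart, oend)), orow["strand"])
                n_multi += 1
            for _dup in range(duplication):
                rid = f"read{next(read_counter):08d}"
                n_aln = 2 if alt is not None else 1
                rows.append((rid, row["chrom"], pos, row["strand"], umi, n_aln))
                if alt is not None:
                    rows.append((rid, alt[0], alt[1], alt[2], umi, n_aln))

    table = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    gt = GroundTruth(
        label="umi_alignments",
        params={
            "molecules": true_counts,
            "total_molecules": int(sum(true_counts.values())),
            "umi_length": umi_length,
            "multimap_fraction": multimap_fraction,
            "duplication": duplication,
            "n_multimapped_molecules": n_multi,
        },
        seed=seed,
    )
    return table, gt


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

DEFAULT_SIZE_MODEL = {
    "fscw_g1_mean": 50.0,
    "fscw_g2_mean": 100.0,
    "fscw_sd": 8.0,
    "sscw_mean": 60.0,
    "sscw_sd": 8.0,
}
DEFAULT_AUTOFLUOR = {"intercept": 5.0, "fscw": 0.2, "sscw": 0.1, "density": 0.001}


def simulate_cytometry_events(
    n: int,
    g1_fraction: float = 0.6,
    size_model: dict | None = None,
    autofluorescence: dict | None = None,
    true_signal: tuple[float, float] = (0.0, 0.0),
    density: float = 1000.0,
    flow_rate: float = 1.0,
    dilution_constant: float = 1.0,
    measurement_sd: float = 1.0,
    channel: str = "GFP",
    seed: int = 0,
) -> tuple[EventTable, GroundTruth]:
    """Cytometry events with bimodal FSC-W and size-dependent autofluorescence.

    ``true_signal`` is (mean, CV) of a log-normal fluorophore signal (mean 0
    means an unlabeled control). Measured fluorescence = true signal +
    linear autofluorescence in (FSC-W, SSC-W, density) + Gaussian noise.
    Acquisition metadata (R, T, N, C) is chosen consistently with the
    requested cell density: T = N * C / (R * density).
    """
    if n < 100:
        raise ParameterError("need >= 100 events (gating undefined on tiny samples)")
    if not 0 < g1_fraction < 1:
        raise ParameterError("g1_fraction must be in (0, 1)")
    sm = {**DEFAULT_SIZE_MODEL, **(size_model or {})}
    af = {**DEFAULT_AUTOFLUOR, **(autofluorescence or {})}
    rng = np.random.default_rng(seed)

    is_g1 = rng.random(n) < g1_fraction
    fscw = np.where(
        is_g1,
        rng.normal(sm["fscw_g1_mean"], sm["fscw_sd"], n),
        rng.normal(sm["fscw_g2_mean"], sm["fscw_sd"], n),
    )
    sscw = rng.normal(sm["sscw_mean"], sm["sscw_sd"], n)
    fsca = 100.0 + 2.0 * fscw + rng.normal(0.0, 10.0, n)
    ssca = 0.8 * fsca + rng.normal(0.0, 5.0, n)

    sig_mean, sig_cv = true_signal
    if sig_mean > 0:
        sigma2 = np.log1p(sig_cv**2)
        mu = np.log(sig_mean) - sigma2 / 2.0
        signal = rng.lognormal(mu, np.sqrt(sigma2), n)
    else:
        signal = np.zeros(n)
    autofl = af["intercept"] + af["fscw"] * fscw + af["sscw"] * sscw + af["density"] * density
    fluor = signal + autofl + rng.normal(0.0, measurement_sd, n)

    events = pd.DataFrame(
        {"FSC-A": fsca, "SSC-A": ssca, "FSC-W": fscw, "SSC-W": sscw, channel: fluor}
    )
    T = n * dilution_constant / (flow_rate * density)
    table = EventTable(
        events=events,
        meta={"R": flow_rate, "T": T, "N": n, "C": dilution_constant, "channel": channel},
    )
    gt = GroundTruth(
        label="cytometry_events",
        params={
            "g1_fraction": g1_fraction,
            "size_model": sm,
            "autofluorescence": af,
            "signal_mean": sig_mean,
            "signal_cv": sig_cv,
            "density": density,
            "measurement_sd": measurement_sd,
            "channel": channel,
        },
        seed=seed,
    )
    return table, gt


# ---------------------------------------------------------------------------
# Growth curves and competition
# ---------------------------------------------------------------------------

def simulate_growth_and_competition(
    x0: float = 0.01,
    K: float = 1.0,
    r: float = 0.5,
    lag: float = 2.0,
    od_noise: float = 0.0,
    t_max: float = 24.0,
    dt: float = 0.5,
    fitness_ratio: float = 1.0,
    n_dilutions: int = 10,
    dilution_factor: float = 8.0,
    initial_freq: float = 0.5,
    freq_noise: float = 0.0,
    seed: int = 0,
) -> tuple[GrowthCurve, pd.DataFrame, GroundTruth]:
    """Lag-shifted logistic OD curve plus a competition frequency series.

    The OD inflection (maximal slope) sits at lag + ln(K/x0 - 1)/r. The
    competition series multiplies the mutant/WT odds by 2^(g*(f-1)) per
    passage, where g = log2(dilution_factor) generations and f is the
    mutant's division rate relative to WT.
    """
    if not (r > 0 and K > x0 > 0):
        raise ParameterError("require r > 0 and K > x0 > 0")
    if not 0 < initial_freq < 1:
        raise ParameterError("initial_freq must be in (0, 1)")
    if dilution_factor <= 1:
        raise ParameterError("dilution_factor must exceed 1")
    rng = np.random.default_rng(seed)

    t = np.arange(0.0, t_max + dt / 2, dt)
    od = np.where(
        t < lag, x0, K / (1.0 + (K / x0 - 1.0) * np.exp(-r * np.clip(t - lag, 0, None)))
    )
    if od_noise > 0:
        od = od + rng.normal(0.0, od_noise, size=od.shape)
    curve = GrowthCurve(time=t, od=od)

    g = np.log2(dilution_factor)
    odds = initial_freq / (1.0 - initial_freq)
    recs = [(0, 1.0, initial_freq)]
    for p in range(1, n_dilutions + 1):
        odds *= 2.0 ** (g * (fitness_ratio - 1.0))
        freq = odds / (1.0 + odds)
        if freq_noise > 0:
            freq = float(np.clip(freq + rng.normal(0.0, freq_noise), 1e-6, 1 - 1e-6))
        recs.append((p, dilution_factor, freq))
    comp = pd.DataFrame(recs, columns=["passage", "dilution_factor", "freq_mutant"])
    comp["freq_wt"] = 1.0 - comp["freq_mutant"]

    gt = GroundTruth(
        label="growth_competition",
        params={
            "x0": x0, "K": K, "r": r, "lag": lag, "od_noise": od_noise,
            "inflection_time": lag + np.log(K / x0 - 1.0) / r,
            "fitness_ratio": fitness_ratio,
            "generations_per_passage": g,
            "total_generations": g * n_dilutions,
            "freq_noise": freq_noise,
        },
        seed=seed,
    )
    return curve, comp, gt


# ---------------------------------------------------------------------------
# Toy genome and ChEC binding tracks
# ---------------------------------------------------------------------------

def make_toy_genome(
    n_genes: int = 8,
    promoter_len: int = 700,
    gene_len: int = 300,
    planted_kmer: str | None = None,
    n_plant: int = 8,
    chrom: str = "chrI",
    seed: int = 0,
) -> tuple[dict, GenomeAnnotation, GroundTruth]:
    """Random toy genome: alternating promoter/gene blocks on one '+' chromosome.

    Optionally plants ``planted_kmer`` at ``n_plant`` random promoter
    positions (recorded in the ground truth).
    """
    rng = np.random.default_rng(seed)
    block = promoter_len + gene_len
    length = n_genes * block
    seq = rng.choice(_BASES, size=length)
    genes = []
    promoter_bounds = []
    for i in range(n_genes):
        tss = i * block + promoter_len
        end3 = tss + gene_len - 1
        genes.append((f"g{i:03d}", chrom, "+", tss, end3))
        promoter_bounds.append((i * block, tss))

    planted_at = []
    if planted_kmer:
        kmer = np.array(list(planted_kmer.upper()))
        k = len(kmer)
        choices = rng.permutation(n_genes)[: min(n_plant, n_genes)]
        for gi in choices:
            lo, hi = promoter_bounds[gi]
            off = int(rng.integers(lo + 20, hi - k - 20))
            seq[off : off + k] = kmer
            planted_at.append(off)

    genome = {chrom: "".join(seq)}
    ann = GenomeAnnotation(
        genes=pd.DataFrame(genes, columns=["gene", "chrom", "strand", "tss", "end3"]),
        chrom_lengths={chrom: length},
    )
    gt = GroundTruth(
        label="toy_genome",
        params={
            "n_genes": n_genes,
            "promoter_len": promoter_len,
            "gene_len": gene_len,
            "planted_kmer": planted_kmer,
            "planted_positions": planted_at,
        },
        seed=seed,
    )
    return genome, ann, gt


def simulate_chec_track(
    genome: dict,
    annotation: GenomeAnnotation,
    planted_kmer: str,
    enrichment: float = 20.0,
    reads: int = 50_000,
    flank: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Read-start alignments with a planted 7-mer binding preference.

    Read 5' positions are drawn with probability proportional to 1 within
    promoters and to ``enrichment`` within +/- ``flank`` bp of each planted
    k-mer occurrence (either strand) inside promoters.
    """
    from .chec import define_promoters  # local import avoids a cycle

    if enrichment <= 0:
        raise ParameterError("enrichment must be positive")
    promoters = define_promoters(annotation)
    kmer = planted_kmer.upper()
    k = len(kmer)
    rc = kmer[::-1].translate(str.maketrans("ACGT", "TGCA"))
    rng = np.random.default_rng(seed)

    weights = {c: np.zeros(len(s)) for c, s in genome.items()}
    occ_total = 0
    occurrences = []
    for _, p in promoters.iterrows():
        if p["end"] <= p["start"]:
            continue
        chrom, s, e = p["chrom"], int(p["start"]), int(p["end"])
        weights[chrom][s:e] = np.maximum(weights[chrom][s:e], 1.0)
        seq = genome[chrom][s:e].upper()
        for pat in {kmer, rc}:
            start = seq.find(pat)
            while start != -1:
                occ_total += 1
                occurrences.append((chrom, s + start))
                lo = max(s + start - flank, s)
                hi = min(s + start + k + flank, e)
                weights[chrom][lo:hi] = enrichment
                start = seq.find(pat, start + 1)
    if occ_total < 5:
        raise ParameterError(
            f"planted k-mer occurs only {occ_total} times within promoters (need >= 5)"
        )

    if reads > 0:
        chroms = list(weights)
        flat = np.concatenate([weights[c] for c in chroms])
        draws = rng.choice(flat.size, size=reads, p=flat / flat.sum())
        offsets = np.cumsum([0] + [len(weights[c]) for c in chroms])
        ci = np.searchsorted(offsets, draws, side="right") - 1
        table = pd.DataFrame(
            {
                "read_id": [f"chec{j:08d}" for j in range(reads)],
                "chrom": np.asarray(chroms, dtype=object)[ci],
                "pos": draws - offsets[ci],
                "strand": "+",
                "umi": "",
                "n_alignments": 1,
            }
        )[ALIGNMENT_COLUMNS]
    else:
        table = pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    gt = GroundTruth(
        label="chec_track",
        params={
            "planted_kmer": kmer,
            "enrichment": enrichment,
            "reads": reads,
            "flank": flank,
            "n_occurrences": occ_total,
            "occurrences": occurrences,
        },
        seed=seed,
    )
    return table, gt
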