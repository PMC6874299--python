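"""Shared container types for the duplinoise pipelines.

Most heavy tabular data travels as :class:`pandas.DataFrame`; the dataclasses
here add the metadata and invariants the analysis stages rely on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Column order of an alignment table (SAM-like TSV with UMI tags).
ALIGNMENT_COLUMNS = ["read_id", "chrom", "pos", "strand", "umi", "n_alignments"]


class ParameterError(ValueError):
    """A generator or analysis parameter violates its precondition."""


class EmptyInputError(ValueError):
    """An operation received an empty table/track it cannot score."""


@dataclass(frozen=True)
class GroundTruth:
    """Provenance record attached to every synthetic dataset.

    ``params`` stores the true generative parameters (rates, pulse times,
    fitness ratios, planted motifs, ...) so downstream recovery tests can
    compute expected values without re-deriving them.
    """

    label: str
    params: dict
    seed: int

    def to_json_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {"label": self.label, "params": _clean(self.params), "seed": int(self.seed)}


@dataclass
class CountVector:
    """Per-cell mRNA molecule counts for one gene in one condition."""

    counts: np.ndarray
    gene: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ParameterError("counts must be one-dimensional")
        if self.counts.size and (
            np.any(self.counts < 0) or not np.allclose(self.counts, np.round(self.counts))
        ):
            raise ParameterError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return int(self.counts.size)


@dataclass
class ImageStack:
    """Multi-channel time-lapse stack: channel -> (T, H, W) float array."""

    frames: dict
    frame_interval: float = 1.0
    missing_frames: frozenset = frozenset()

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.frames.values()}
        if len(shapes) > 1:
            raise ParameterError("all channels must share (T, H, W)")
        self.frames = {c: np.asarray(a, dtype=float) for c, a in self.frames.items()}
        self.missing_frames = frozenset(int(i) for i in self.missing_frames)

    @property
    def n_frames(self) -> int:
        return next(iter(self.frames.values())).shape[0]

    @property
    def channels(self) -> list:
        return list(self.frames)


@dataclass
class CellRecord:
    """A segmented cell: static mask plus per-frame area / quality series."""

    cell_id: int
    mask: np.ndarray  # (H, W) bool
    area: np.ndarray  # (T,) pixels; NaN when the cell is absent
    seg_score: np.ndarray  # (T,) unitless, higher is better
    present_from: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area = np.asarray(self.area, dtype=float)
        self.seg_score = np.asarray(self.seg_score, dtype=float)


@dataclass
class TraceSet:
    """Per-cell nuclear-localization ratio series, per channel.

    ``raw[channel]`` is an (n_cells, n_frames) array of nucleus/cytoplasm
    mean-intensity ratios. ``normalized`` divides each cell by its own
    minimum (so min == 1 exactly); ``zscored`` standardizes each cell's
    normalized series; ``amplitude`` is the max of the normalized series.
    """

    raw: dict
    cell_ids: np.ndarray
    frame_interval: float = 1.0
    normalized: Optional[dict] = None
    zscored: Optional[dict] = None
    amplitude: Optional[dict] = None

    def __post_init__(self) -> None:
        self.raw = {c: np.asarray(a, dtype=float) for c, a in self.raw.items()}
        self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return next(iter(self.raw.values())).shape[0]

    @property
    def n_frames(self) -> int:
        return next(iter(self.raw.values())).shape[1]

    @property
    def channels(self) -> list:
        return list(self.raw)


@dataclass
class GenomeAnnotation:
    """Minimal gene annotation: per-gene chrom/strand/TSS/3' end (0-based)."""

    genes: pd.DataFrame  # columns: gene, chrom, strand, tss, end3
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "strand", "tss", "end3"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ParameterError(f"annotation missing columns: {sorted(missing)}")
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise ParameterError("strand must be '+' or '-'")
        # TSS upstream of the 3' end in strand orientation
        plus = self.genes["strand"] == "+"
        if (plus & (self.genes["tss"] >= self.genes["end3"])).any():
            raise ParameterError("on '+' strand TSS must precede the 3' end")
        if (~plus & (self.genes["tss"] <= self.genes["end3"])).any():
            raise ParameterError("on '-' strand TSS must follow the 3' end")
        self.genes = self.genes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def row(self, gene: str) -> pd.Series:
        hit = self.genes[self.genes["gene"] == gene]
        if hit.empty:
            raise KeyError(gene)
        return hit.iloc[0]


@dataclass
class EventTable:
    """Flow-cytometry events with acquisition metadata.

    ``meta`` carries R (flow rate, ul/s), T (total flow time, s), N (events)
    and C (dilution fix constant, 1 or 1.8333 by convention).
    """

    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta = dict(self.meta)
        self.meta.setdefault("N", len(self.events))

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class NoiseSummary:
    mean: float
    cv2: float
    n_events: int
    flagged: bool = False


@dataclass
class GrowthCurve:
    """Blank-subtracted OD time series for one well/replicate."""

    time: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    replicate: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.size != self.od.size:
            raise ParameterError("time and od must have equal length")
        if self.time.size < 5:
            raise ParameterError("need at least 5 OD points")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")


@dataclass
class ExpressionTimecourse:
    """Gene x timepoint matrix of normalized reads (per 1e6) for one strain."""

    values: pd.DataFrame  # index: gene, columns: timepoints (minutes, increasing)
    raw_totals: pd.Series  # per-timepoint raw read totals
    discarded: list = field(default_factory=list)
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        cols = np.asarray(self.values.columns, dtype=float)
        if np.any(np.diff(cols) <= 0):
            raise ParameterError("timepoints must be strictly increasing")
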