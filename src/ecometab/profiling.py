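"""Meta-omics profiling: from alignment evidence to abundance/activity matrices.

The chain implemented here mirrors standard genome-resolved profiling of
paired metagenomes (DNA) and metatranscriptomes (RNA):

1. alignments are filtered on mapping quality and nucleotide identity,
   where identity ignores ambiguous reference bases:
   ``identity = 1 - (NM - XN) / L`` with NM the edit distance, XN the
   number of ambiguous (N) reference bases in the alignment and L the
   read length;
2. per genome and sample, depth (vertical coverage, mapped bases divided
   by genome length) and breadth (horizontal coverage, fraction of
   positions covered at least once) are accumulated;
3. a genome is *observed* in a sample when its metagenomic breadth is at
   least 30%; its abundance is the metagenomic depth (optionally
   normalized per million mapped sample bases) and its activity the
   ratio of metatranscriptomic over metagenomic depth;
4. genomes observed in fewer than ``n_obs_min`` samples are dropped,
   independently per layer, and the matrices are CLR-transformed per
   sample with an adaptive pseudo-count (half the smallest nonzero value
   of the sample) before network inference.

Alignment spans use 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord",
    "OmicsMatrix",
    "alignment_identity",
    "filter_alignments",
    "coverage_from_alignments",
    "detect_genome",
    "abundance",
    "activity",
    "build_matrices",
    "clr_transform",
]

MIN_MAPQ = 20
MIN_IDENTITY = 0.95
BREADTH_MIN = 0.30
N_OBS_MIN = 10


@dataclass(frozen=True)
class AlignmentRecord:
    """A summarized read alignment (SAM NM/XN tags, not the sequence)."""

    read_id: str
    genome_id: str
    L: int
    NM: int
    XN: int
    MAPQ: int
    sample_id: str = "S1"
    start: int = 0
    end: int = 0  # 0 means "use start + L"

    def __post_init__(self) -> None:
        if not 0 <= self.XN <= self.NM <= self.L:
            raise ValueError(
                f"invalid alignment counts: 0 <= XN({self.XN}) <= NM({self.NM})"
                f" <= L({self.L}) violated"
            )
        if self.MAPQ < 0:
            raise ValueError("MAPQ must be >= 0")

    @property
    def span(self) -> tuple[int, int]:
        end = self.end if self.end > self.start else self.start + self.L
        return (self.start, end)


def alignment_identity(rec: AlignmentRecord) -> float:
    """Nucleotide identity of an alignment, ignoring ambiguous reference bases.

    The mismatch fraction is ``(NM - XN) / L``; identity is its complement,
    so an identity threshold of 95% keeps alignments whose non-ambiguous
    edit load is at most 5% of the read length.
    """
    if rec.L == 0:
        raise ValueError("zero-length read")
    return 1.0 - (rec.NM - rec.XN) / rec.L


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_mapq: int = MIN_MAPQ,
    min_identity: float = MIN_IDENTITY,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Keep alignments with MAPQ >= min_mapq and identity >= min_identity.

    Both thresholds are inclusive. Returns the kept records and a per-genome
    table of kept/discarded counts.
    """
    kept: list[AlignmentRecord] = []
    counts: dict[str, list[int]] = {}
    for rec in records:
        ok = rec.MAPQ >= min_mapq and alignment_identity(rec) >= min_identity
        row = counts.setdefault(rec.genome_id, [0, 0])
        if ok:
            kept.append(rec)
            row[0] += 1
        else:
            row[1] += 1
    report = pd.DataFrame(
        [(g, k, d) for g, (k, d) in sorted(counts.items())],
        columns=["genome_id", "kept", "discarded"],
    )
    return kept, report


def _merge_spans(spans: list[tuple[int, int]]) -> int:
    """Total number of positions covered by a union of half-open spans."""
    covered = 0
    cur_start, cur_end = None, None
    for s, e in sorted(spans):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def coverage_from_alignments(
    records: Iterable[AlignmentRecord],
    genome_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Depth and breadth per genome and sample from (filtered) alignments.

    depth = sum of aligned bases / genome length; breadth = fraction of
    genome positions covered at least once (positions counted once).
    """
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for rec in records:
        if rec.genome_id not in genome_lengths:
            raise KeyError(f"unknown genome: {rec.genome_id}")
        spans.setdefault((rec.genome_id, rec.sample_id), []).append(rec.span)
    rows = []
    for (gid, sid), sp in sorted(spans.items()):
        length = genome_lengths[gid]
        total = sum(e - s for s, e in sp)
        rows.append(
            {
                "genome_id": gid,
                "sample_id": sid,
                "depth": total / length,
                "breadth": _merge_spans(sp) / length,
            }
        )
    return pd.DataFrame(rows, columns=["genome_id", "sample_id", "depth", "breadth"])


def detect_genome(breadth: float, breadth_min: float = BREADTH_MIN) -> bool:
    """A genome is present in a sample when breadth >= 30% (inclusive)."""
    if not 0.0 <= breadth <= 1.0:
        raise ValueError(f"breadth out of [0,1]: {breadth}")
    return breadth >= breadth_min


def abundance(depth_mg: float, sample_scale: float) -> float:
    """Depth normalized by sequencing effort (per million mapped sample bases).

    ``sample_scale`` is the sample's total mapped bases divided by 1e6;
    passing 1.0 disables cross-sample normalization.
    """
    if depth_mg < 0:
        raise ValueError("depth must be >= 0")
    if sample_scale <= 0:
        if depth_mg > 0:
            raise ValueError("zero sample total with nonzero depth")
        return 0.0
    return depth_mg / sample_scale


def activity(depth_mt: float, depth_mg: float) -> float:
    """Genome activity: metatranscriptomic over metagenomic vertical coverage.

    Zero activity is allowed (a present genome with no detected
    transcription); a present genome with zero metagenomic depth is an
    inconsistent input.
    """
    if depth_mg <= 0:
        raise ValueError("present genome with non-positive metagenomic depth")
    return depth_mt / depth_mg


@dataclass
class OmicsMatrix:
    """Genomes x samples values with explicit missing-value semantics.

    ``values`` holds the layer quantity; ``mask`` is True where the genome
    is observed (breadth rule) in the sample. Unobserved cells never enter
    any downstream statistic.
    """

    layer: str
    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in ("abundance", "activity"):
            raise ValueError(f"unknown layer: {self.layer}")
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must be aligned")

    @property
    def masked_values(self) -> pd.DataFrame:
        """Values with unobserved cells as NaN."""
        return self.values.where(self.mask)

    def n_observations(self) -> pd.Series:
        return self.mask.sum(axis=1)


def _pivot(cov: pd.DataFrame, column: str) -> pd.DataFrame:
    return cov.pivot_table(
        index="genome_id", columns="sample_id", values=column, aggfunc="first"
    )


def build_matrices(
    cov_mg: pd.DataFrame,
    cov_mt: pd.DataFrame | None = None,
    genome_lengths: Mapping[str, int] | None = None,
    breadth_min: float = BREADTH_MIN,
    n_obs_min: int = N_OBS_MIN,
    normalization: str = "sample_million_bases",
) -> tuple[OmicsMatrix, OmicsMatrix | None]:
    """Build the abundance and activity matrices from coverage tables.

    Parameters
    ----------
    cov_mg, cov_mt : long tables (genome_id, sample_id, depth, breadth)
        Metagenomic and metatranscriptomic coverage. ``cov_mt`` may be
        None, in which case only the abundance matrix is returned.
    genome_lengths : required for the ``sample_million_bases`` abundance
        normalization (total mapped bases per sample = sum of
        depth * genome length over genomes).
    normalization : {"sample_million_bases", "none"}
        Cross-sample sequencing-effort normalization of the abundance
        layer. Activity is a within-sample depth ratio and is not affected.

    A cell is observed when the metagenomic breadth is >= ``breadth_min``;
    genomes with fewer than ``n_obs_min`` observed cells are dropped,
    independently per layer. The activity matrix is restricted to samples
    present in both layers.
    """
    if normalization not in ("sample_million_bases", "none"):
        raise ValueError(f"unknown normalization: {normalization}")
    depth_mg = _pivot(cov_mg, "depth").fillna(0.0)
    breadth_mg = _pivot(cov_mg, "breadth").fillna(0.0)
    observed = breadth_mg >= breadth_min

    if normalization == "sample_million_bases":
        if genome_lengths is None:
            raise ValueError("genome_lengths required for sample_million_bases")
        lengths = pd.Series(genome_lengths).reindex(depth_mg.index)
        if lengths.isna().any():
            raise KeyError("genome_lengths missing some genomes")
        totals = depth_mg.mul(lengths, axis=0).sum(axis=0) / 1e6
        totals = totals.replace(0.0, np.nan)
        abund_values = depth_mg.div(totals, axis=1).fillna(0.0)
    else:
        abund_values = depth_mg.copy()

    keep_ab = observed.sum(axis=1) >= n_obs_min
    abundance_matrix = OmicsMatrix(
        "abundance",
        abund_values.loc[keep_ab].sort_index(),
        observed.loc[keep_ab].sort_index(),
    )

    if cov_mt is None:
        return abundance_matrix, None

    depth_mt = _pivot(cov_mt, "depth")
    shared = sorted(set(depth_mg.columns) & set(depth_mt.columns))
    if not shared:
        raise ValueError("no samples shared between metaG and metaT layers")
    depth_mt = depth_mt.reindex(index=depth_mg.index, columns=shared).fillna(0.0)
    dg = depth_mg[shared]
    obs = observed[shared]
    if bool((obs & (dg <= 0)).any().any()):
        raise ValueError("present genome with zero metagenomic depth")
    act = (depth_mt / dg.where(dg > 0)).where(obs, 0.0)
    keep_act = obs.sum(axis=1) >= n_obs_min
    activity_matrix = OmicsMatrix(
        "activity", act.loc[keep_act].sort_index(), obs.loc[keep_act].sort_index()
    )
    return abundance_matrix, activity_matrix


def clr_transform(
    matrix: OmicsMatrix | pd.DataFrame, mask: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Centred log-ratio transform, per sample, over observed genomes only.

    Zeros among observed values are replaced by an adaptive pseudo-count:
    half the smallest nonzero observed value of that sample. Transformed
    observed values of each sample sum to zero; unobserved cells are NaN.
    """
    if isinstance(matrix, OmicsMatrix):
        values, mask = matrix.values, matrix.mask
    else:
        values = matrix
        if mask is None:
            mask = pd.DataFrame(True, index=values.index, columns=values.columns)
    if (values.values[mask.values] < 0).any():
        raise ValueError("CLR requires non-negative values")
    out = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    for sample in values.columns:
        col = values[sample][mask[sample]]
        if col.empty:
            continue
        nonzero = col[col > 0]
        if nonzero.empty:
            raise ValueError(f"sample {sample!r} has all-zero observed values")
        pseudo = nonzero.min() / 2.0
        logs = np.log(col.replace(0.0, pseudo))
        out.loc[logs.index, sample] = logs - logs.mean()
    return out
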