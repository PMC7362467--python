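"""Chromatographic fingerprint similarity analysis.

An HPLC fingerprint panel defines a set of *common peaks* present in every
sample of a cohort (28 for rhubarb).  One well-separated peak — No. 13 by
default — serves as the *reference peak*: dividing every peak's retention
time and area by the reference peak's values yields the relative retention
times and relative peak areas that make fingerprints comparable across runs.

Similarity between two fingerprints is the included-angle cosine of their
relative-area vectors (Pearson correlation is available as an alternative).
The *reference similarity index* (RSI) of a sample is its similarity to the
mean fingerprint of the whole cohort; samples with high RSI form group A,
samples with low RSI group B, and RSI values falling between the two
thresholds are left unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "CommonPeakMatrix",
    "FingerprintVector",
    "SimilarityResult",
    "relative_quantities",
    "mean_reference_fingerprint",
    "similarity",
    "similarity_matrix",
    "classify_by_rsi",
    "read_peak_table_csv",
    "build_common_peak_matrix",
]

DEFAULT_REFERENCE_PEAK = 13
# RSI group thresholds: >= high -> A, <= low -> B, between -> unassigned
DEFAULT_HIGH_THRESHOLD = 0.885
DEFAULT_LOW_THRESHOLD = 0.84


@dataclass(frozen=True)
class PeakTable:
    """Peak list of one sample: (peak_id, retention time [min], area)."""

    sample_id: str
    peaks: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate peak_ids in sample {self.sample_id!r}")
        ordered = sorted(self.peaks)
        rts = [p[1] for p in ordered]
        if any(rt <= 0 for rt in rts):
            raise ValueError("retention times must be positive")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError(
                f"retention times must increase with peak_id in sample {self.sample_id!r}"
            )
        if any(p[2] < 0 for p in self.peaks):
            raise ValueError("peak areas must be non-negative")
        object.__setattr__(self, "peaks", tuple(ordered))


@dataclass(frozen=True)
class CommonPeakMatrix:
    """Cohort-level sample × common-peak matrices of areas and retention times."""

    sample_ids: tuple[str, ...]
    peak_ids: tuple[int, ...]
    areas: np.ndarray
    retention_times: np.ndarray
    reference_peak_id: int = DEFAULT_REFERENCE_PEAK

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        rts = np.asarray(self.retention_times, dtype=float)
        shape = (len(self.sample_ids), len(self.peak_ids))
        if areas.shape != shape or rts.shape != shape:
            raise ValueError("matrix shapes must be (n_samples, n_peaks)")
        if np.any(areas < 0):
            raise ValueError("areas must be non-negative")
        if np.any(rts <= 0):
            raise ValueError("retention times must be positive")
        if self.reference_peak_id not in self.peak_ids:
            raise ValueError(f"reference peak {self.reference_peak_id} not in peak_ids")
        ref = self.peak_ids.index(self.reference_peak_id)
        bad = np.asarray(self.sample_ids)[areas[:, ref] <= 0]
        if bad.size:
            raise ValueError(
                f"reference peak {self.reference_peak_id} has zero area in "
                f"sample(s): {', '.join(bad)}"
            )
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "retention_times", rts)

    @property
    def reference_index(self) -> int:
        return self.peak_ids.index(self.reference_peak_id)


@dataclass(frozen=True)
class FingerprintVector:
    """Per-sample relative areas and relative retention times.

    The entry at the reference peak equals exactly 1 for both vectors.
    """

    sample_id: str
    peak_ids: tuple[int, ...]
    relative_areas: np.ndarray
    relative_rts: np.ndarray
    reference_peak_id: int = DEFAULT_REFERENCE_PEAK

    def __post_init__(self) -> None:
        ra = np.asarray(self.relative_areas, dtype=float)
        rr = np.asarray(self.relative_rts, dtype=float)
        if ra.shape != (len(self.peak_ids),) or rr.shape != (len(self.peak_ids),):
            raise ValueError("vector lengths must match peak_ids")
        object.__setattr__(self, "relative_areas", ra)
        object.__setattr__(self, "relative_rts", rr)


@dataclass(frozen=True)
class SimilarityResult:
    """Pairwise similarity matrix, per-sample RSI and group labels."""

    sample_ids: tuple[str, ...]
    pairwise: np.ndarray
    rsi: np.ndarray
    groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pairwise, dtype=float)
        n = len(self.sample_ids)
        if p.shape != (n, n):
            raise ValueError("pairwise matrix must be square over sample_ids")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("pairwise matrix must be symmetric")
        if not np.allclose(np.diag(p), 1.0, atol=1e-9):
            raise ValueError("pairwise diagonal must be 1")
        object.__setattr__(self, "pairwise", p)
        object.__setattr__(self, "rsi", np.asarray(self.rsi, dtype=float))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(pairwise matrix, per-sample RSI/group table) as DataFrames."""
        ids = list(self.sample_ids)
        pw = pd.DataFrame(self.pairwise, index=ids, columns=ids)
        rsi = pd.DataFrame(
            {
                "sample_id": ids,
                "rsi": self.rsi,
                "group": self.groups if self.groups is not None else [""] * len(ids),
            }
        )
        return pw, rsi


def read_peak_table_csv(path) -> list[PeakTable]:
    """Read long-format peak tables: columns sample_id,peak_id,rt_min,area."""
    df = pd.read_csv(path)
    required = {"sample_id", "peak_id", "rt_min", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak CSV must have columns {sorted(required)}")
    return [
        PeakTable(
            sample_id=str(sid),
            peaks=tuple(
                (int(r.peak_id), float(r.rt_min), float(r.area))
                for r in grp.itertuples()
            ),
        )
        for sid, grp in df.groupby("sample_id", sort=True)
    ]


def build_common_peak_matrix(
    tables: Sequence[PeakTable],
    peak_ids: Sequence[int] | None = None,
    reference_peak_id: int = DEFAULT_REFERENCE_PEAK,
) -> CommonPeakMatrix:
    """Assemble per-sample peak tables into a common-peak matrix.

    A common peak missing from a sample is imputed as area 0 (with a logged
    warning) at the cohort-median retention time of that peak; the reference
    peak may never be missing.
    """
    if not tables:
        raise ValueError("need at least one peak table")
    if peak_ids is None:
        peak_ids = sorted({pid for t in tables for pid, _, _ in t.peaks})
    peak_ids = tuple(int(p) for p in peak_ids)
    sample_ids = tuple(t.sample_id for t in tables)
    n, m = len(sample_ids), len(peak_ids)
    areas = np.zeros((n, m))
    rts = np.full((n, m), np.nan)
    for i, t in enumerate(tables):
        lookup = {pid: (rt, area) for pid, rt, area in t.peaks}
        for j, pid in enumerate(peak_ids):
            if pid in lookup:
                rts[i, j], areas[i, j] = lookup[pid]
            else:
                if pid == reference_peak_id:
                    raise ValueError(
                        f"reference peak {pid} missing from sample {t.sample_id!r}"
                    )
                logger.warning(
                    "common peak %d missing in sample %s; imputing area 0",
                    pid,
                    t.sample_id,
                )
    # fill missing retention times with the cohort median for that peak
    col_median = np.nanmedian(rts, axis=0)
    rts = np.where(np.isnan(rts), col_median, rts)
    return CommonPeakMatrix(
        sample_ids=sample_ids,
        peak_ids=peak_ids,
        areas=areas,
        retention_times=rts,
        reference_peak_id=reference_peak_id,
    )


def relative_quantities(matrix: CommonPeakMatrix) -> list[FingerprintVector]:
    """Relative areas and retention times against the reference peak."""
    ref = matrix.reference_index
    out = []
    for i, sid in enumerate(matrix.sample_ids):
        ref_area = matrix.areas[i, ref]
        ref_rt = matrix.retention_times[i, ref]
        if ref_area <= 0:
            raise ValueError(f"zero reference-peak area in sample {sid!r}")
        out.append(
            FingerprintVector(
                sample_id=sid,
                peak_ids=matrix.peak_ids,
                relative_areas=matrix.areas[i] / ref_area,
                relative_rts=matrix.retention_times[i] / ref_rt,
                reference_peak_id=matrix.reference_peak_id,
            )
        )
    return out


def mean_reference_fingerprint(
    vectors: Sequence[FingerprintVector],
    statistic: Literal["mean", "median"] = "mean",
) -> FingerprintVector:
    """Standard (mean-reference) fingerprint: per-peak average of the cohort."""
    if not vectors:
        raise ValueError("need at least one fingerprint vector")
    peak_ids = vectors[0].peak_ids
    if any(v.peak_ids != peak_ids for v in vectors):
        raise ValueError("fingerprint vectors have inconsistent peak sets")
    agg = np.mean if statistic == "mean" else np.median
    return FingerprintVector(
        sample_id="__mean_reference__",
        peak_ids=peak_ids,
        relative_areas=agg([v.relative_areas for v in vectors], axis=0),
        relative_rts=agg([v.relative_rts for v in vectors], axis=0),
        reference_peak_id=vectors[0].reference_peak_id,
    )


def _similarity_values(
    u: np.ndarray, v: np.ndarray, method: Literal["cosine", "correlation"]
) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cannot compute similarity of a zero-norm vector")
    if method == "cosine":
        return float(np.dot(u, v) / (nu * nv))
    if method == "correlation":
        uc, vc = u - u.mean(), v - v.mean()
        du, dv = np.linalg.norm(uc), np.linalg.norm(vc)
        if du == 0 or dv == 0:
            raise ValueError("correlation undefined for a constant vector")
        return float(np.dot(uc, vc) / (du * dv))
    raise ValueError(f"unknown similarity method {method!r}")


def similarity(
    u: FingerprintVector,
    v: FingerprintVector,
    method: Literal["cosine", "correlation"] = "cosine",
) -> float:
    """Similarity of two fingerprints on their relative-area vectors, in [-1, 1]."""
    if u.peak_ids != v.peak_ids:
        raise ValueError("fingerprints cover different peak sets")
    return _similarity_values(u.relative_areas, v.relative_areas, method)


def similarity_matrix(
    vectors: Sequence[FingerprintVector],
    method: Literal["cosine", "correlation"] = "cosine",
    high_threshold: float | None = None,
    low_threshold: float | None = None,
) -> SimilarityResult:
    """Pairwise similarities plus each sample's RSI to the mean fingerprint.

    If both thresholds are given, group labels are assigned from the RSI.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two fingerprint vectors")
    X = np.vstack([v.relative_areas for v in vectors])
    ids = tuple(v.sample_id for v in vectors)
    n = len(vectors)
    pairwise = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = _similarity_values(X[i], X[j], method)
            except ValueError as exc:
                raise ValueError(f"samples {ids[i]!r}/{ids[j]!r}: {exc}") from exc
            pairwise[i, j] = pairwise[j, i] = s
    mean_fp = mean_reference_fingerprint(vectors)
    rsi = np.array(
        [_similarity_values(X[i], mean_fp.relative_areas, method) for i in range(n)]
    )
    groups = None
    if high_threshold is not None and low_threshold is not None:
        groups = classify_by_rsi(rsi, high_threshold, low_threshold)
    return SimilarityResult(sample_ids=ids, pairwise=pairwise, rsi=rsi, groups=groups)


def classify_by_rsi(
    rsi: Sequence[float],
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
    low_threshold: float = DEFAULT_LOW_THRESHOLD,
) -> tuple[str, ...]:
    """Two-group assignment from the reference similarity index.

    ``rsi >= high_threshold`` → "A"; ``rsi <= low_threshold`` → "B"; values in
    the open gap are labelled "unassigned" with a warning.
    """
    if low_threshold > high_threshold:
        raise ValueError("low_threshold must not exceed high_threshold")
    rsi = np.asarray(rsi, dtype=float)
    if np.any((rsi < -1 - 1e-12) | (rsi > 1 + 1e-12)):
        raise ValueError("RSI values must lie in [-1, 1]")
    labels = []
    for value in rsi:
        if value >= high_threshold:
            labels.append("A")
        elif value <= low_threshold:
            labels.append("B")
        else:
            logger.warning("RSI %.3f falls between thresholds; leaving unassigned", value)
            labels.append("unassigned")
    return tuple(labels)
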