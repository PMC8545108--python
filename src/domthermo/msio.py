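"""Peak-list ingestion and the cross-sample data-reduction funnel.

Per-sample FT-ICR MS peak lists (m/z, intensity, signal-to-noise) pass
through a fixed sequence of reductions before formula assignment:

1. signal-to-noise filter (peaks with S/N below a threshold are discarded),
2. blank subtraction (peaks matching a procedural blank within a ppm
   tolerance are removed),
3. cross-sample alignment into consensus peaks (single-linkage in sorted
   mass order with a ppm gap threshold), and
4. an occurrence filter keeping consensus peaks seen in a minimum number of
   samples, which removes the long tail of singleton masses.

Peak counts are monotone non-increasing through the funnel.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    sn: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.sn < 0:
            raise ValueError("S/N must be non-negative")


@dataclass
class PeakList:
    """One sample's peaks, kept strictly sorted by m/z."""

    sample_id: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        for a, b in zip(self.peaks, self.peaks[1:]):
            if b.mz <= a.mz:
                raise ValueError(
                    f"duplicate m/z {b.mz} in sample {self.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


@dataclass
class AlignedPeakMatrix:
    """Consensus peaks x samples after cross-sample alignment.

    ``occurrence[i, j]`` is True exactly where ``intensity[i, j] > 0``;
    ``provenance[i]`` lists the (sample_id, original m/z) pairs merged into
    consensus peak i.
    """

    consensus_mz: np.ndarray
    sample_ids: list[str]
    intensity: np.ndarray
    provenance: list[list[tuple[str, float]]]

    @property
    def occurrence(self) -> np.ndarray:
        return self.intensity > 0

    @property
    def n_peaks(self) -> int:
        return len(self.consensus_mz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensity, index=pd.Index(self.consensus_mz, name="consensus_mz"),
            columns=self.sample_ids,
        )


DEFAULT_DIALECT = {"mz": "mz", "intensity": "intensity", "sn": "sn"}


def read_peak_list(
    path: str | Path,
    sample_id: str | None = None,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> PeakList:
    """Read a delimited peak list (CSV/TSV, optionally gzipped).

    ``dialect`` maps the logical columns ``mz``, ``intensity``, ``sn`` to the
    file's header names.  Duplicated m/z values are rejected: a well-formed
    centroided peak list has one entry per resolved mass.
    """
    path = Path(path)
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    if sep is None:
        sep = "\t" if ".tsv" in path.suffixes or path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [v for v in dialect.values() if v not in df.columns]
    if missing:
        raise KeyError(f"{path}: missing required column(s) {missing}")
    peaks = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            peaks.append(
                Peak(
                    mz=float(rec[dialect["mz"]]),
                    intensity=float(rec[dialect["intensity"]]),
                    sn=float(rec[dialect["sn"]]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric value on line {i}: {exc}") from exc
    return PeakList(sample_id or path.stem, peaks)


def write_peak_list(pl: PeakList, path: str | Path) -> None:
    pd.DataFrame(
        {"mz": [p.mz for p in pl.peaks],
         "intensity": [p.intensity for p in pl.peaks],
         "sn": [p.sn for p in pl.peaks]}
    ).to_csv(path, index=False)


def filter_sn(pl: PeakList, threshold: float = 6.0) -> PeakList:
    """Discard peaks with S/N strictly below ``threshold`` (default 6)."""
    if threshold <= 0:
        raise ValueError("S/N threshold must be positive")
    return PeakList(pl.sample_id, [p for p in pl.peaks if p.sn >= threshold])


def _ppm_match(mz: float, targets: np.ndarray, tol_ppm: float) -> bool:
    if targets.size == 0:
        return False
    i = np.searchsorted(targets, mz)
    for j in (i - 1, i):
        if 0 <= j < targets.size:
            if abs(mz - targets[j]) / mz * 1e6 <= tol_ppm:
                return True
    return False


def subtract_blanks(
    pl: PeakList, blanks: Iterable[PeakList], tol_ppm: float = 1.0
) -> PeakList:
    """Remove peaks matching any procedural-blank peak within ``tol_ppm``."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    blanks = list(blanks)
    if blanks:
        blank_mz = np.sort(np.concatenate([b.mz for b in blanks]))
    else:
        blank_mz = np.array([])
    kept = [p for p in pl.peaks if not _ppm_match(p.mz, blank_mz, tol_ppm)]
    return PeakList(pl.sample_id, kept)


def align_peaks(lists: Sequence[PeakList], tol_ppm: float = 1.0) -> AlignedPeakMatrix:
    """Cluster all samples' peaks into consensus peaks along the mass axis.

    Single-linkage over the pooled, mass-sorted peaks: consecutive peaks
    belong to the same cluster iff their relative gap is at most ``tol_ppm``.
    The consensus mass is the intensity-weighted mean of the members.  When a
    cluster holds two peaks from one sample, the more intense one represents
    that sample (a warning is logged).  The result is invariant to the order
    in which samples are supplied.
    """
    if not lists:
        raise ValueError("need at least one peak list")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    sample_ids = sorted(pl.sample_id for pl in lists)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    col = {sid: j for j, sid in enumerate(sample_ids)}

    pooled = sorted(
        ((p.mz, p.intensity, pl.sample_id) for pl in lists for p in pl.peaks),
        key=lambda t: (t[0], t[2]),
    )
    if not pooled:
        return AlignedPeakMatrix(np.array([]), sample_ids, np.zeros((0, len(sample_ids))), [])

    clusters: list[list[tuple[float, float, str]]] = [[pooled[0]]]
    for prev, cur in zip(pooled, pooled[1:]):
        gap_ppm = (cur[0] - prev[0]) / prev[0] * 1e6
        if gap_ppm <= tol_ppm:
            clusters[-1].append(cur)
        else:
            clusters.append([cur])

    consensus_mz = np.empty(len(clusters))
    intensity = np.zeros((len(clusters), len(sample_ids)))
    provenance: list[list[tuple[str, float]]] = []
    for i, members in enumerate(clusters):
        mzs = np.array([m[0] for m in members])
        ints = np.array([m[1] for m in members])
        consensus_mz[i] = float(np.average(mzs, weights=ints)) if ints.sum() > 0 else float(mzs.mean())
        provenance.append([(m[2], m[0]) for m in members])
        seen: dict[str, float] = {}
        for mz, inten, sid in members:
            if sid in seen:
                logger.warning(
                    "sample %s contributes two peaks to consensus %.5f; keeping the more intense",
                    sid, consensus_mz[i],
                )
                inten = max(inten, seen[sid])
            seen[sid] = inten
        for sid, inten in seen.items():
            intensity[i, col[sid]] = inten
    return AlignedPeakMatrix(consensus_mz, sample_ids, intensity, provenance)


def occurrence_filter(m: AlignedPeakMatrix, min_count: int = 6) -> AlignedPeakMatrix:
    """Keep consensus peaks observed in at least ``min_count`` samples."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keep = m.occurrence.sum(axis=1) >= min_count
    return AlignedPeakMatrix(
        m.consensus_mz[keep],
        list(m.sample_ids),
        m.intensity[keep],
        [prov for prov, k in zip(m.provenance, keep) if k],
    )


def write_peak_matrix(m: AlignedPeakMatrix, path: str | Path, provenance_path: str | Path | None = None) -> None:
    """Write the matrix as wide TSV; optionally a provenance sidecar TSV."""
    # %.17g round-trips IEEE doubles exactly
    m.to_frame().reset_index().to_csv(path, sep="\t", float_format="%.17g", index=False)
    if provenance_path is not None:
        rows = [
            {"consensus_index": i, "sample_id": sid, "member_mz": mz}
            for i, members in enumerate(m.provenance)
            for sid, mz in members
        ]
        pd.DataFrame(rows, columns=["consensus_index", "sample_id", "member_mz"]).to_csv(
            provenance_path, sep="\t", index=False
        )


def read_peak_matrix(path: str | Path, provenance_path: str | Path | None = None) -> AlignedPeakMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    provenance: list[list[tuple[str, float]]] = [[] for _ in range(len(df))]
    if provenance_path is not None:
        prov = pd.read_csv(provenance_path, sep="\t")
        for _, row in prov.iterrows():
            provenance[int(row["consensus_index"])].append(
                (str(row["sample_id"]), float(row["member_mz"]))
            )
    return AlignedPeakMatrix(
        df.index.to_numpy(dtype=float), [str(c) for c in df.columns],
        df.to_numpy(dtype=float), provenance,
    )
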