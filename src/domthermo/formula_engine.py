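"""CHNOSP molecular-formula assignment for ultrahigh-resolution mass spectra.

Each consensus peak (an exact neutral monoisotopic mass known to ~1 ppm) is
matched against every elemental composition C_c H_h N_n O_o S_s P_p allowed by
a set of per-element limits.  When several candidate formulas fall inside the
mass tolerance, a deterministic rule picks one: heteroatom parsimony first
(fewest N+S+P), then smallest absolute mass error, with a lexicographic final
tie-break.  A phosphorus atom is only accepted when at least four oxygen atoms
accompany it, reflecting the phosphate/phosphonate chemistry of natural
organic matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# Monoisotopic masses (Da), pinned for reproducibility.
MASS_C = 12.0
MASS_H = 1.007825032
MASS_N = 14.003074005
MASS_O = 15.994914620
MASS_S = 31.972071174
MASS_P = 30.973761998
PROTON_MASS = 1.007276467

_ELEMENT_MASSES = np.array([MASS_C, MASS_H, MASS_N, MASS_O, MASS_S, MASS_P])


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """An elemental composition C/H/N/O/S/P with net charge ``z``.

    Field order (c, h, n, o, s, p) defines the lexicographic ordering used as
    the deterministic final tie-break in candidate selection.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0
    z: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative atom count for {name}")

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da (charge ignored; z is bookkeeping)."""
        return (
            self.c * MASS_C
            + self.h * MASS_H
            + self.n * MASS_N
            + self.o * MASS_O
            + self.s * MASS_S
            + self.p * MASS_P
        )

    @property
    def heteroatoms(self) -> int:
        """Number of non-CHO atoms (N + S + P), the parsimony criterion."""
        return self.n + self.s + self.p

    def counts(self) -> tuple[int, int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s, self.p)

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical N/O/P/S)."""
        parts = []
        for sym, cnt in (
            ("C", self.c),
            ("H", self.h),
            ("N", self.n),
            ("O", self.o),
            ("P", self.p),
            ("S", self.s),
        ):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)

    @classmethod
    def from_hill(cls, text: str, z: int = 0) -> "MolecularFormula":
        import re

        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0, "P": 0}
        pos = 0
        for m in re.finditer(r"([CHNOSP])(\d*)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(
            c=counts["C"], h=counts["H"], n=counts["N"],
            o=counts["O"], s=counts["S"], p=counts["P"], z=z,
        )

    def __str__(self) -> str:
        return self.hill()


@dataclass(frozen=True)
class ElementLimits:
    """Inclusive per-element atom-count bounds for the formula search."""

    c: tuple[int, int] = (0, 100)
    h: tuple[int, int] = (0, 200)
    o: tuple[int, int] = (0, 30)
    n: tuple[int, int] = (0, 4)
    s: tuple[int, int] = (0, 2)
    p: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        for name in ("c", "h", "o", "n", "s", "p"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid limits for {name}: ({lo}, {hi})")


DEFAULT_LIMITS = ElementLimits()


@dataclass
class Assignment:
    """Outcome of formula assignment for one consensus peak."""

    consensus_mz: float
    neutral_mass: float
    formula: MolecularFormula | None
    error_ppm: float = math.nan
    n_candidates: int = 0


def neutral_mass(mz: float, mode: str = "negative") -> float:
    """Convert an observed m/z to the neutral monoisotopic mass.

    ``negative`` assumes deprotonation ([M-H]^-, the electrospray mode used
    for natural organic matter), ``positive`` protonation ([M+H]^+).
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if mode == "negative":
        return mz + PROTON_MASS
    if mode == "positive":
        return mz - PROTON_MASS
    raise ValueError(f"unsupported ionization mode: {mode!r}")


def decompose_mass(
    neutral: float,
    tol_ppm: float = 1.0,
    limits: ElementLimits = DEFAULT_LIMITS,
) -> list[MolecularFormula]:
    """Enumerate every formula within ``limits`` matching ``neutral`` mass.

    The tolerance is strict: a candidate is returned iff
    ``|mass - neutral| / neutral * 1e6 < tol_ppm``.  The search is exhaustive
    within the limits; pruning only removes compositions that provably cannot
    reach the mass window.  Returns an empty list when nothing matches.
    """
    if tol_ppm <= 0:
        return []
    tol_da = neutral * tol_ppm * 1e-6
    h_lo, h_hi = limits.h
    grid = _heavy_grid(limits)
    # Hydrogen count is recovered by inversion: for any fixed heavy-atom
    # composition only h = round(residual / m_H) (+/- 1 for safety) can land
    # inside a sub-mDa window, since m_H >> tol.  Compositions whose residual
    # falls outside the reachable hydrogen-mass span are pruned up front.
    residual = neutral - grid.mass
    reach = (residual >= h_lo * MASS_H - tol_da) & (residual <= h_hi * MASS_H + tol_da)
    idx = np.nonzero(reach)[0]
    found: set[tuple[int, int, int, int, int, int]] = set()
    res = residual[idx]
    h_near = np.rint(res / MASS_H).astype(int)
    for dh in (0, -1, 1):
        h = h_near + dh
        ok = (h >= h_lo) & (h <= h_hi) & (np.abs(res - h * MASS_H) < tol_da)
        for k in np.nonzero(ok)[0]:
            j = idx[k]
            found.add(
                (int(grid.c[j]), int(h[k]), int(grid.n[j]),
                 int(grid.o[j]), int(grid.s[j]), int(grid.p[j]))
            )
    out = [MolecularFormula(c=c, h=hh, n=n, o=o, s=s, p=p)
           for c, hh, n, o, s, p in found]
    out.sort()
    return out


def select_formula(
    candidates: Sequence[MolecularFormula],
    errors_ppm: Sequence[float],
) -> MolecularFormula | None:
    """Pick the single best candidate, or ``None``.

    Rules, in order: (1) drop phosphorus-bearing candidates with fewer than
    four oxygens; (2) fewest heteroatoms (N+S+P); (3) smallest |error|;
    (4) lexicographic (c,h,n,o,s,p) as a deterministic last resort.
    Carbon-free compositions are never assigned.
    """
    if len(candidates) != len(errors_ppm):
        raise ValueError("candidates and errors must align")
    survivors = [
        (f, e)
        for f, e in zip(candidates, errors_ppm)
        if f.c >= 1 and not (f.p >= 1 and f.o < 4)
    ]
    if not survivors:
        return None
    survivors.sort(key=lambda fe: (fe[0].heteroatoms, abs(fe[1]), fe[0].counts()))
    return survivors[0][0]


def assign_peak(
    mz: float,
    tol_ppm: float = 1.0,
    limits: ElementLimits = DEFAULT_LIMITS,
    mode: str = "negative",
) -> Assignment:
    """Assign one observed m/z: neutralize, decompose, select."""
    neutral = neutral_mass(mz, mode)
    cands = decompose_mass(neutral, tol_ppm, limits)
    errors = [(f.monoisotopic_mass - neutral) / neutral * 1e6 for f in cands]
    best = select_formula(cands, errors)
    if best is None:
        return Assignment(mz, neutral, None, n_candidates=len(cands))
    err = (best.monoisotopic_mass - neutral) / neutral * 1e6
    return Assignment(mz, neutral, best, error_ppm=err, n_candidates=len(cands))


def assign_matrix(
    matrix,
    tol_ppm: float = 1.0,
    limits: ElementLimits = DEFAULT_LIMITS,
    mode: str = "negative",
) -> list[Assignment]:
    """Assign every consensus peak of an :class:`~domthermo.msio.AlignedPeakMatrix`.

    Returns one :class:`Assignment` per consensus mass, in mass order; peaks
    with no acceptable formula carry ``formula=None`` and are dropped from
    downstream thermodynamic scoring.
    """
    return [assign_peak(mz, tol_ppm, limits, mode) for mz in matrix.consensus_mz]


def brute_force_decompose(
    neutral: float,
    tol_ppm: float = 1.0,
    limits: ElementLimits = DEFAULT_LIMITS,
) -> list[MolecularFormula]:
    """Reference enumeration over the full Cartesian composition grid.

    No pruning and no hydrogen inversion: every (c,h,n,o,s,p) tuple in the
    limits is massed and filtered.  Exists as an independent oracle for
    :func:`decompose_mass`; far too slow for production use on wide limits.
    """
    grid = _full_mass_grid(limits)
    tol_da = neutral * tol_ppm * 1e-6
    hits = np.nonzero(np.abs(grid - neutral) < tol_da)
    offsets = [limits.c[0], limits.h[0], limits.n[0], limits.o[0], limits.s[0], limits.p[0]]
    out = [
        MolecularFormula(
            c=int(ci) + offsets[0], h=int(hi) + offsets[1], n=int(ni) + offsets[2],
            o=int(oi) + offsets[3], s=int(si) + offsets[4], p=int(pi) + offsets[5],
        )
        for ci, hi, ni, oi, si, pi in zip(*hits)
    ]
    out.sort()
    return out


@dataclass(frozen=True)
class _HeavyGrid:
    """Flat arrays of every (c, n, o, s, p) combination and its mass."""

    c: np.ndarray
    n: np.ndarray
    o: np.ndarray
    s: np.ndarray
    p: np.ndarray
    mass: np.ndarray


_HEAVY_CACHE: dict[ElementLimits, _HeavyGrid] = {}


def _heavy_grid(limits: ElementLimits) -> _HeavyGrid:
    grid = _HEAVY_CACHE.get(limits)
    if grid is None:
        c, n, o, s, p = (
            a.ravel()
            for a in np.meshgrid(
                np.arange(limits.c[0], limits.c[1] + 1),
                np.arange(limits.n[0], limits.n[1] + 1),
                np.arange(limits.o[0], limits.o[1] + 1),
                np.arange(limits.s[0], limits.s[1] + 1),
                np.arange(limits.p[0], limits.p[1] + 1),
                indexing="ij",
            )
        )
        mass = c * MASS_C + n * MASS_N + o * MASS_O + s * MASS_S + p * MASS_P
        grid = _HeavyGrid(c, n, o, s, p, mass)
        _HEAVY_CACHE[limits] = grid
    return grid


_GRID_CACHE: dict[ElementLimits, np.ndarray] = {}


def _full_mass_grid(limits: ElementLimits) -> np.ndarray:
    grid = _GRID_CACHE.get(limits)
    if grid is None:
        axes = []
        for (lo, hi), m in zip(
            (limits.c, limits.h, limits.n, limits.o, limits.s, limits.p),
            _ELEMENT_MASSES,
        ):
            axes.append(np.arange(lo, hi + 1) * m)
        grid = (
            axes[0][:, None, None, None, None, None]
            + axes[1][None, :, None, None, None, None]
            + axes[2][None, None, :, None, None, None]
            + axes[3][None, None, None, :, None, None]
            + axes[4][None, None, None, None, :, None]
            + axes[5][None, None, None, None, None, :]
        )
        _GRID_CACHE[limits] = grid
    return grid
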