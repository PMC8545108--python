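"""Thermodynamic quality of organic-matter compounds.

The nominal oxidation state of carbon (NOSC) of a molecule C_c H_h N_n O_o
S_s P_p with net charge Z is

    NOSC = 4 - (-Z + 4c + h - 3n - 2o + 5p - 2s) / c

and the standard-state Gibbs free energy of the carbon-oxidation half
reaction, per mole of carbon (not per mole of substrate), follows the
empirical linear relation

    dG_Cox = 60.3 - 28.5 * NOSC   [kJ (mol C)^-1].

Higher dG_Cox means a thermodynamically less favorable substrate: under
standard conditions its oxidation is endergonic and must be coupled to a
terminal electron acceptor.  A sample's substrate quality is summarized by
the median dG_Cox over its assigned compounds.

Compounds are additionally binned into elemental classes (CHO, CHNO, ...)
and, via their molar H/C and O/C ratios, into van Krevelen biochemical
classes (lipid, protein, carbohydrate, lignin, tannin, condensed aromatic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formula_engine import MolecularFormula

DGCOX_INTERCEPT = 60.3  # kJ per mol C at NOSC = 0
DGCOX_SLOPE = -28.5     # kJ per mol C per NOSC unit


def nosc(f: MolecularFormula) -> float:
    """Nominal oxidation state of carbon; undefined for carbon-free species."""
    if f.c < 1:
        raise ValueError("NOSC is undefined for a carbon-free composition")
    return 4.0 - (-f.z + 4 * f.c + f.h - 3 * f.n - 2 * f.o + 5 * f.p - 2 * f.s) / f.c


def dgcox(nosc_value: float) -> float:
    """Gibbs free energy of carbon oxidation, kJ per mol C."""
    return DGCOX_INTERCEPT + DGCOX_SLOPE * nosc_value


ELEMENTAL_CLASSES = ("CHO", "CHNO", "CHOS", "CHNOS", "P-containing", "other")


def elemental_class(f: MolecularFormula) -> str:
    """Elemental class label: P-containing compounds form their own class,
    otherwise the concatenation of elements present in C,H,N,O,S order."""
    if f.c < 1:
        raise ValueError("elemental class requires at least one carbon")
    if f.p >= 1:
        return "P-containing"
    label = "".join(
        sym for sym, cnt in (("C", f.c), ("H", f.h), ("N", f.n), ("O", f.o), ("S", f.s))
        if cnt > 0
    )
    return label if label in ELEMENTAL_CLASSES else (label or "other")


@dataclass(frozen=True)
class VKBoundary:
    """One van Krevelen rectangle: half-open in H/C and O/C unless noted."""

    label: str
    oc: tuple[float, float]
    hc: tuple[float, float]
    oc_closed_hi: bool = False  # include the upper O/C edge (used at O/C = 1.2)
    requires_n: bool = False


# Priority-ordered default boundary table.  H/C in [lo, hi), O/C in [lo, hi)
# (or [lo, hi] where the upper edge is closed).  Users may substitute any
# published scheme via `vk_class(..., boundaries=...)`.
DEFAULT_VK_TABLE: tuple[VKBoundary, ...] = (
    VKBoundary("lipid", oc=(0.0, 0.3), hc=(1.5, 2.5)),
    VKBoundary("protein", oc=(0.3, 0.67), hc=(1.5, 2.3), requires_n=True),
    VKBoundary("carbohydrate", oc=(0.67, 1.2), hc=(1.5, 2.5), oc_closed_hi=True),
    VKBoundary("lignin", oc=(0.1, 0.67), hc=(0.7, 1.5)),
    VKBoundary("tannin", oc=(0.67, 1.2), hc=(0.5, 1.5), oc_closed_hi=True),
    VKBoundary("condensed aromatic", oc=(0.0, 0.67), hc=(0.2, 0.7)),
)

VK_CLASSES = tuple(b.label for b in DEFAULT_VK_TABLE) + ("unassigned",)


def vk_class(
    f: MolecularFormula,
    boundaries: Sequence[VKBoundary] = DEFAULT_VK_TABLE,
) -> str:
    """Van Krevelen biochemical class by H/C x O/C rectangle lookup.

    The first matching rectangle in priority order wins; points outside all
    rectangles are "unassigned".
    """
    if f.c < 1:
        raise ValueError("ratios require at least one carbon")
    hc = f.h / f.c
    oc = f.o / f.c
    for b in boundaries:
        oc_hi_ok = oc <= b.oc[1] if b.oc_closed_hi else oc < b.oc[1]
        if (
            b.oc[0] <= oc and oc_hi_ok
            and b.hc[0] <= hc < b.hc[1]
            and (f.n >= 1 or not b.requires_n)
        ):
            return b.label
    return "unassigned"


@dataclass
class CompoundRecord:
    """A formula with its thermodynamic score and class labels."""

    formula: MolecularFormula
    nosc: float
    dgcox: float
    hc_ratio: float
    oc_ratio: float
    elemental_class: str
    vk_class: str

    @classmethod
    def from_formula(
        cls,
        f: MolecularFormula,
        boundaries: Sequence[VKBoundary] = DEFAULT_VK_TABLE,
    ) -> "CompoundRecord":
        nv = nosc(f)
        return cls(
            formula=f,
            nosc=nv,
            dgcox=dgcox(nv),
            hc_ratio=f.h / f.c,
            oc_ratio=f.o / f.c,
            elemental_class=elemental_class(f),
            vk_class=vk_class(f, boundaries),
        )


@dataclass
class SampleThermo:
    sample_id: str
    median_dgcox: float
    n_compounds: int
    class_proportions: dict[str, float]


def sample_median_dg(
    sample_id: str,
    records: Sequence[CompoundRecord],
    class_field: str = "elemental_class",
) -> SampleThermo:
    """Median dG_Cox and class proportions over one sample's compounds."""
    if not records:
        raise ValueError(f"sample {sample_id!r} has no assigned compounds")
    values = np.array([r.dgcox for r in records])
    labels = [getattr(r, class_field) for r in records]
    counts = pd.Series(labels).value_counts()
    props = (counts / counts.sum()).to_dict()
    return SampleThermo(
        sample_id=sample_id,
        median_dgcox=float(np.median(values)),
        n_compounds=len(records),
        class_proportions=props,
    )


def compounds_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabulate compound records (one row per formula) for TSV export."""
    return pd.DataFrame(
        [
            {
                "formula": r.formula.hill(),
                "nosc": r.nosc,
                "dgcox": r.dgcox,
                "hc_ratio": r.hc_ratio,
                "oc_ratio": r.oc_ratio,
                "elemental_class": r.elemental_class,
                "vk_class": r.vk_class,
            }
            for r in records
        ]
    )


def sample_thermo_table(
    matrix,
    assignments,
    boundaries: Sequence[VKBoundary] = DEFAULT_VK_TABLE,
) -> pd.DataFrame:
    """Per-sample thermodynamic summary from an aligned matrix + assignments.

    Only consensus peaks that received a formula contribute.  Returns a frame
    indexed by sample with median dG_Cox, compound count, and elemental-class
    proportions.
    """
    assigned = [(i, a) for i, a in enumerate(assignments) if a.formula is not None]
    recs = {i: CompoundRecord.from_formula(a.formula, boundaries) for i, a in assigned}
    rows = []
    for j, sid in enumerate(matrix.sample_ids):
        present = [recs[i] for i, _ in assigned if matrix.occurrence[i, j]]
        st = sample_median_dg(sid, present)
        row = {"sample_id": sid, "median_dgcox": st.median_dgcox, "n_compounds": st.n_compounds}
        for cls in ELEMENTAL_CLASSES:
            row[f"prop_{cls}"] = st.class_proportions.get(cls, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
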