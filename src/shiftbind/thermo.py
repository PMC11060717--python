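"""Bivalency thermodynamics: fold enhancements and binding free-energy gains.

Comparing the dissociation constant of a complex against a monovalent or
unphosphorylated reference gives a fold enhancement Kd_ref/Kd and the
corresponding standard free-energy difference ddG = -RT ln(fold).
Component contributions (e.g. the two phosphate groups of a doubly
phosphorylated tail) add in ddG and multiply in fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3

#: default experiment temperature (25 C)
T_DEFAULT_K = 298.15


class KdSource(str, Enum):
    CSP_FIT = "csp_fit"
    LINESHAPE_EXTERNAL = "lineshape_external"
    LITERATURE = "literature"


class Site(str, Enum):
    WW = "WW"
    PPIASE = "PPIase"
    BIVALENT = "bivalent"


@dataclass(frozen=True)
class KdRecord:
    """One measured dissociation constant with its provenance."""

    complex_label: str
    site: Site
    Kd: float
    source: KdSource = KdSource.CSP_FIT

    def __post_init__(self) -> None:
        if not self.Kd > 0:
            raise ValidationError(f"Kd must be > 0, got {self.Kd}")
        if not isinstance(self.site, Site):
            object.__setattr__(self, "site", Site(self.site))
        if not isinstance(self.source, KdSource):
            object.__setattr__(self, "source", KdSource(self.source))


def fold_enhancement(Kd_reference: float, Kd: float) -> float:
    """Affinity enhancement Kd_reference / Kd (dimensionless)."""
    if Kd_reference <= 0 or Kd <= 0:
        raise ValidationError(
            f"dissociation constants must be > 0, got {Kd_reference}, {Kd}"
        )
    return Kd_reference / Kd


def delta_delta_g(fold: float, temperature_K: float = T_DEFAULT_K) -> float:
    """Standard binding free-energy difference -RT ln(fold), kcal/mol.

    fold > 1 (an enhancement) gives a negative ddG.
    """
    if fold <= 0:
        raise ValidationError(f"fold must be > 0, got {fold}")
    if temperature_K <= 0:
        raise ValidationError(f"temperature must be > 0 K, got {temperature_K}")
    return -R_KCAL * temperature_K * math.log(fold)


@dataclass(frozen=True)
class BivalencyRow:
    comparison_label: str
    Kd_reference: float
    Kd: float
    fold: float
    ddG: float


@dataclass
class BivalencySummary:
    """Ledger of Kd comparisons with folds and free-energy contributions."""

    rows: list[BivalencyRow]
    temperature_K: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison_label": r.comparison_label,
                    "Kd_reference_uM": r.Kd_reference,
                    "Kd_uM": r.Kd,
                    "fold": r.fold,
                    "ddG_kcal_mol": r.ddG,
                }
                for r in self.rows
            ]
        )

    def to_json(self, path) -> None:
        payload = {
            "temperature_K": self.temperature_K,
            "R_kcal_mol_K": R_KCAL,
            "rows": [r.__dict__ for r in self.rows],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def bivalency_report(
    records: Iterable[KdRecord],
    comparisons: Sequence[tuple[str, str]],
    temperature_K: float = T_DEFAULT_K,
    include_additivity: bool = False,
) -> BivalencySummary:
    """Build the bivalency ledger from Kd records.

    ``comparisons`` lists (reference_label, label) pairs; each compared
    label must occur exactly once among the records.  With
    ``include_additivity`` a final row multiplies the component folds and
    sums their ddG values.
    """
    records = list(records)
    by_label: dict[str, KdRecord] = {}
    for rec in records:
        if rec.complex_label in by_label:
            raise ValidationError(f"duplicate Kd record for label {rec.complex_label!r}")
        by_label[rec.complex_label] = rec
    rows: list[BivalencyRow] = []
    for ref_label, label in comparisons:
        for lab in (ref_label, label):
            if lab not in by_label:
                raise KeyError(f"no Kd record for label {lab!r}")
        kd_ref, kd = by_label[ref_label].Kd, by_label[label].Kd
        fold = fold_enhancement(kd_ref, kd)
        rows.append(
            BivalencyRow(
                comparison_label=f"{ref_label} vs {label}",
                Kd_reference=kd_ref,
                Kd=kd,
                fold=fold,
                ddG=delta_delta_g(fold, temperature_K),
            )
        )
    if include_additivity and rows:
        fold_total = math.prod(r.fold for r in rows)
        rows.append(
            BivalencyRow(
                comparison_label="combined (product of folds, sum of ddG)",
                Kd_reference=math.nan,
                Kd=math.nan,
                fold=fold_total,
                ddG=sum(r.ddG for r in rows),
            )
        )
    return BivalencySummary(rows=rows, temperature_K=temperature_K)
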