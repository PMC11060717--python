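"""Core data model and tabular I/O for titration and EXSY experiments.

A titration experiment is stored as one CSV table: five metadata columns
(``residue_id``, ``residue_name``, ``domain``, ``fast_exchange``,
``resolved``) followed by one ``(delta_H_<k>, delta_N_<k>)`` column pair per
titration point, with point 0 the apo reference.  Total concentrations live
in a small JSON experiment config, the single source of truth for P0 and the
ligand schedule.  Missing peaks (overlapped or exchange-broadened cross-peaks
at a given ligand concentration) are encoded with the ``NA`` token, never as
silent zeros.

Units: concentrations in uM, chemical shifts in ppm, mixing times in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, field_validator

from .errors import DimensionError, FormatError, ValidationError

NA_TOKEN = "NA"

META_COLUMNS = ("residue_id", "residue_name", "domain", "fast_exchange", "resolved")


class Domain(str, Enum):
    """Structural domain a residue belongs to."""

    WW = "WW"
    PPIASE = "PPIase"
    LINKER = "linker"


@dataclass(frozen=True)
class ResidueShift:
    """Amide cross-peak position of one residue in one spectrum (ppm)."""

    residue_id: int
    residue_name: str
    delta_H: float
    delta_N: float

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValidationError(f"residue_id must be >= 1, got {self.residue_id}")
        if not (math.isfinite(self.delta_H) and math.isfinite(self.delta_N)):
            raise ValidationError(
                f"residue {self.residue_id}: shifts must be finite, "
                f"got delta_H={self.delta_H}, delta_N={self.delta_N}"
            )


@dataclass(frozen=True)
class ResidueMeta:
    """Per-residue experimental annotation.

    ``fast_exchange`` marks residues whose binding response is in the
    fast-exchange regime (observed shift is the population-weighted
    average); ``resolved`` marks residues whose cross-peak is free of
    overlap in every spectrum of the series.
    """

    residue_id: int
    domain: Domain
    fast_exchange: bool
    resolved: bool

    def __post_init__(self) -> None:
        if not isinstance(self.domain, Domain):
            object.__setattr__(self, "domain", Domain(self.domain))


class ExperimentConfig(BaseModel):
    """JSON experiment configuration validated before any computation."""

    protein_conc_uM: float
    ligand_concs_uM: list[float]
    label: str = ""
    temperature_K: float = 298.15

    @field_validator("protein_conc_uM")
    @classmethod
    def _positive_p0(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"protein_conc_uM must be > 0, got {v}")
        return v

    @field_validator("ligand_concs_uM")
    @classmethod
    def _valid_schedule(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("ligand_concs_uM must be non-empty")
        if any(c < 0 for c in v):
            raise ValueError(f"negative ligand concentration in {v}")
        if v[0] != 0:
            raise ValueError("apo reference required: first ligand concentration must be 0")
        return v

    @field_validator("temperature_K")
    @classmethod
    def _positive_t(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"temperature_K must be > 0, got {v}")
        return v


@dataclass
class TitrationDataset:
    """Per-residue shift trajectories across a ligand-concentration series.

    ``shifts`` maps ``(residue_id, conc_index)`` to the observed peak
    position; a missing key is an explicitly missing peak at that point.
    """

    protein_conc_P0: float
    ligand_concs_L0: tuple[float, ...]
    shifts: dict[tuple[int, int], ResidueShift]
    meta: dict[int, ResidueMeta]
    label: str = ""
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        self.ligand_concs_L0 = tuple(float(c) for c in self.ligand_concs_L0)
        self.validate()

    def validate(self) -> None:
        if self.protein_conc_P0 <= 0:
            raise ValidationError(f"P0 must be > 0, got {self.protein_conc_P0}")
        if not self.ligand_concs_L0:
            raise ValidationError("ligand concentration schedule is empty")
        if any(c < 0 for c in self.ligand_concs_L0):
            raise ValidationError(f"negative ligand concentration in {self.ligand_concs_L0}")
        if self.ligand_concs_L0[0] != 0:
            raise ValidationError("apo reference required: first ligand concentration must be 0")
        n = self.n_points
        for (rid, k), shift in self.shifts.items():
            if rid not in self.meta:
                raise ValidationError(f"shift recorded for residue {rid} absent from metadata")
            if not 0 <= k < n:
                raise ValidationError(f"conc_index {k} out of range for residue {rid}")
            if shift.residue_id != rid:
                raise ValidationError(
                    f"shift residue_id {shift.residue_id} disagrees with key {rid}"
                )

    @property
    def n_points(self) -> int:
        return len(self.ligand_concs_L0)

    @property
    def residues(self) -> list[int]:
        return sorted(self.meta)

    def shift_at(self, residue_id: int, conc_index: int) -> Optional[ResidueShift]:
        return self.shifts.get((residue_id, conc_index))

    def with_seed_label(self, label: str) -> "TitrationDataset":
        return replace(self, label=label)


@dataclass
class ExsyCurve:
    """EXSY cross-peak/diagonal intensity-ratio buildup vs. mixing time."""

    mixing_times: tuple[float, ...]
    ratio_ct: tuple[float, ...]
    I_tt: Optional[tuple[float, ...]] = None
    I_ct: Optional[tuple[float, ...]] = None
    I_cc: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        self.mixing_times = tuple(float(t) for t in self.mixing_times)
        self.ratio_ct = tuple(float(r) for r in self.ratio_ct)
        if len(self.mixing_times) != len(self.ratio_ct):
            raise ValidationError("mixing_times and ratio_ct must have equal length")
        if any(t < 0 for t in self.mixing_times):
            raise ValidationError("mixing times must be >= 0")
        if any(b <= a for a, b in zip(self.mixing_times, self.mixing_times[1:])):
            raise ValidationError("mixing times must be strictly increasing")
        if any(r < 0 for r in self.ratio_ct):
            raise ValidationError("intensity ratios must be >= 0")
        for name in ("I_tt", "I_ct", "I_cc"):
            vals = getattr(self, name)
            if vals is None:
                continue
            vals = tuple(float(v) for v in vals)
            setattr(self, name, vals)
            if len(vals) != len(self.mixing_times):
                raise ValidationError(f"{name} length disagrees with mixing_times")
            if any(v < 0 for v in vals):
                raise ValidationError(f"negative intensity in {name}")

    def __len__(self) -> int:
        return len(self.mixing_times)


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool,)):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise FormatError(f"column {column!r}, row {row}: cannot parse boolean from {value!r}")


def read_titration_table(path, config: ExperimentConfig | Mapping) -> TitrationDataset:
    """Read a titration CSV; ``config`` supplies P0 and the ligand schedule."""
    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig(**dict(config))
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False, dtype=object)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"malformed header: missing required column {col!r}")
    n_pairs = 0
    while f"delta_H_{n_pairs}" in df.columns:
        if f"delta_N_{n_pairs}" not in df.columns:
            raise FormatError(f"malformed header: delta_H_{n_pairs} lacks its delta_N_{n_pairs} pair")
        n_pairs += 1
    if n_pairs == 0:
        raise FormatError("malformed header: no delta_H_0/delta_N_0 shift columns found")
    if n_pairs != len(config.ligand_concs_uM):
        raise DimensionError(
            f"{n_pairs} shift column pairs but {len(config.ligand_concs_uM)} "
            "ligand concentrations in config"
        )
    meta: dict[int, ResidueMeta] = {}
    shifts: dict[tuple[int, int], ResidueShift] = {}
    for irow, row in df.iterrows():
        try:
            rid = int(row["residue_id"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"column 'residue_id', row {irow}: {row['residue_id']!r}") from exc
        name = str(row["residue_name"])
        try:
            domain = Domain(str(row["domain"]))
        except ValueError as exc:
            raise ValidationError(f"row {irow}: unknown domain {row['domain']!r}") from exc
        meta[rid] = ResidueMeta(
            residue_id=rid,
            domain=domain,
            fast_exchange=_parse_bool(row["fast_exchange"], "fast_exchange", irow),
            resolved=_parse_bool(row["resolved"], "resolved", irow),
        )
        for k in range(n_pairs):
            h, n15 = row[f"delta_H_{k}"], row[f"delta_N_{k}"]
            if pd.isna(h) or pd.isna(n15):
                continue  # explicitly missing peak at this point
            shifts[(rid, k)] = ResidueShift(rid, name, float(h), float(n15))
    return TitrationDataset(
        protein_conc_P0=config.protein_conc_uM,
        ligand_concs_L0=tuple(config.ligand_concs_uM),
        shifts=shifts,
        meta=meta,
        label=config.label,
        temperature_K=config.temperature_K,
    )


def write_titration_table(ds: TitrationDataset, path) -> None:
    """Write the CSV dialect :func:`read_titration_table` accepts, full precision."""
    if not ds.meta:
        raise ValidationError("nothing to write: dataset has no residues")
    lines = []
    header = list(META_COLUMNS)
    for k in range(ds.n_points):
        header += [f"delta_H_{k}", f"delta_N_{k}"]
    lines.append(",".join(header))
    for rid in ds.residues:
        m = ds.meta[rid]
        name = next(
            (s.residue_name for (r, _), s in ds.shifts.items() if r == rid), "X"
        )
        cells = [str(rid), name, m.domain.value, str(m.fast_exchange), str(m.resolved)]
        for k in range(ds.n_points):
            s = ds.shift_at(rid, k)
            if s is None:
                cells += [NA_TOKEN, NA_TOKEN]
            else:
                cells += [repr(s.delta_H), repr(s.delta_N)]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_exsy_table(path) -> ExsyCurve:
    """Read an EXSY CSV with ``t_mix`` plus either ``ratio_ct`` or raw intensities."""
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    if "t_mix" not in df.columns:
        raise FormatError("malformed header: missing required column 't_mix'")
    t = [float(v) for v in df["t_mix"]]
    if "ratio_ct" in df.columns:
        return ExsyCurve(mixing_times=tuple(t), ratio_ct=tuple(float(v) for v in df["ratio_ct"]))
    if not {"I_tt", "I_ct"} <= set(df.columns):
        raise FormatError("malformed header: need 'ratio_ct' or both 'I_tt' and 'I_ct'")
    itt = [float(v) for v in df["I_tt"]]
    ict = [float(v) for v in df["I_ct"]]
    for i, v in enumerate(itt):
        if v == 0:
            raise ValidationError(f"row {i}: I_tt is zero, ratio I_ct/I_tt undefined")
    icc = tuple(float(v) for v in df["I_cc"]) if "I_cc" in df.columns else None
    ratios = tuple(c / d for c, d in zip(ict, itt))
    return ExsyCurve(
        mixing_times=tuple(t), ratio_ct=ratios,
        I_tt=tuple(itt), I_ct=tuple(ict), I_cc=icc,
    )


def write_exsy_table(curve: ExsyCurve, path) -> None:
    """Write an EXSY curve in the dialect :func:`read_exsy_table` accepts."""
    cols: dict[str, Sequence] = {"t_mix": curve.mixing_times}
    if curve.I_tt is not None and curve.I_ct is not None:
        cols["I_tt"] = curve.I_tt
        cols["I_ct"] = curve.I_ct
        if curve.I_cc is not None:
            cols["I_cc"] = curve.I_cc
    else:
        cols["ratio_ct"] = curve.ratio_ct
    header = ",".join(cols)
    rows = [",".join(repr(float(c[i])) for c in cols.values()) for i in range(len(curve))]
    Path(path).write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
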