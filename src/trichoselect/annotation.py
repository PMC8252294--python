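"""Metabolite feature-table construction and structural annotation.

Acylsugars are named by the field's shorthand ``S{k}:{N}`` / ``G{k}:{N}``: a
sucrose (S) or glucose (G) backbone esterified with ``k`` acyl chains carrying
``N`` carbon atoms in total (e.g. S3:15 is a tri-acylsucrose with 15 acyl
carbons).  For saturated, non-hydroxylated chains the label and the CHO
molecular formula determine each other exactly, which is what makes
annotation from high-resolution parent-ion formulas possible:

* each esterification adds one acid ``CcH2cO2`` and removes one water, i.e.
  ``+C_c, +H_(2c-2), +O_1`` per chain;
* the double-bond equivalent DBE = (2C + 2 - H)/2 counts backbone rings
  (2 for sucrose, 1 for glucose) plus one ester carbonyl per chain, so
  ``k = DBE - rings``.

Volatiles are annotated on the n-alkane retention scale (Kovats index):
under a linear oven ramp the index of a peak is obtained by linear
interpolation between the bracketing alkanes (van den Dool & Kratz).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MolecularFormula",
    "AcylsugarLabel",
    "CalibrationSeries",
    "FeatureTable",
    "AnnotationError",
    "normalize_abundance",
    "kovats_index",
    "label_to_formula",
    "formula_to_label",
    "adduct_mz",
    "build_feature_table",
]

# Monoisotopic masses (CODATA/IUPAC); the electron mass is neglected so the
# nominal printed adduct masses are reproduced.
MASS = {
    "C": 12.000000,
    "H": 1.007825,
    "O": 15.994915,
    "Na": 22.989770,
    "K": 38.963707,
}
# HCOO- = CHO2
_FORMATE = MASS["C"] + MASS["H"] + 2 * MASS["O"]

ADDUCT_SHIFTS = {
    "[M+H]+": MASS["H"],
    "[M+Na]+": MASS["Na"],
    "[M+K]+": MASS["K"],
    "[M+HCOO]-": _FORMATE,
}

_BACKBONES = {
    # backbone -> (C, H, O, ring DBE)
    "S": (12, 22, 11, 2),  # sucrose C12H22O11
    "G": (6, 12, 6, 1),    # glucose C6H12O6
}


class AnnotationError(ValueError):
    """Raised for invalid formulas, labels or calibration inputs."""


@dataclass(frozen=True)
class MolecularFormula:
    """A CHO molecular formula with non-negative atom counts."""

    n_C: int
    n_H: int
    n_O: int

    def __post_init__(self) -> None:
        if min(self.n_C, self.n_H, self.n_O) < 0:
            raise AnnotationError("atom counts must be non-negative")

    @property
    def dbe(self) -> float:
        """Double-bond equivalents, (2C + 2 - H) / 2."""
        return (2 * self.n_C + 2 - self.n_H) / 2

    @property
    def monoisotopic_mass(self) -> float:
        return self.n_C * MASS["C"] + self.n_H * MASS["H"] + self.n_O * MASS["O"]

    def __str__(self) -> str:
        return f"C{self.n_C}H{self.n_H}O{self.n_O}"

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        m = re.fullmatch(r"C(\d+)H(\d+)(?:O(\d+))?", text.strip())
        if m is None:
            raise AnnotationError(f"cannot parse CHO formula {text!r}")
        return cls(int(m.group(1)), int(m.group(2)), int(m.group(3) or 0))


@dataclass(frozen=True)
class AcylsugarLabel:
    """An ``S{k}:{N}`` / ``G{k}:{N}`` acylsugar name, optionally isomer-indexed."""

    backbone: str  # "S" or "G"
    k: int         # number of esterified acyl chains
    N: int         # total acyl carbon atoms
    isomer_index: int | None = None

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONES:
            raise AnnotationError(f"unknown backbone {self.backbone!r} (use S or G)")
        if self.k < 0:
            raise AnnotationError("chain count k must be >= 0")
        if self.k == 0 and self.N != 0:
            raise AnnotationError("no chains implies zero acyl carbons")
        # shortest esterifiable chain is acetyl (2 carbons)
        if self.k > 0 and self.N < 2 * self.k:
            raise AnnotationError(
                f"{self.backbone}{self.k}:{self.N}: needs N >= 2k (acetyl minimum)"
            )

    def __str__(self) -> str:
        base = f"{self.backbone}{self.k}:{self.N}"
        if self.isomer_index is not None:
            return f"{base}-{self.isomer_index}"
        return base

    @classmethod
    def parse(cls, text: str) -> "AcylsugarLabel":
        m = re.fullmatch(r"([SG])(\d+):(\d+)(?:-(\d+))?", text.strip())
        if m is None:
            raise AnnotationError(f"cannot parse acylsugar label {text!r}")
        iso = int(m.group(4)) if m.group(4) else None
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), iso)


def label_to_formula(label: AcylsugarLabel | str) -> MolecularFormula:
    """Molecular formula of a saturated, non-hydroxylated acylsugar.

    Esterifying ``k`` saturated acids with ``N`` total carbons onto the
    backbone adds ``C_N H_(2N-2k) O_k``.
    """
    if isinstance(label, str):
        label = AcylsugarLabel.parse(label)
    bc, bh, bo, _ = _BACKBONES[label.backbone]
    return MolecularFormula(
        bc + label.N, bh + 2 * label.N - 2 * label.k, bo + label.k
    )


def formula_to_label(formula: MolecularFormula | str) -> AcylsugarLabel:
    """Invert :func:`label_to_formula`; reject non-acylsugar formulas.

    Tries both backbones; a CHO formula can match at most one of them
    (their implied H counts differ by 8 at equal C and O).  Unsaturated or
    hydroxylated chains make the H/O bookkeeping fail and are rejected
    rather than guessed.
    """
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    for backbone, (bc, bh, bo, _rings) in _BACKBONES.items():
        k = formula.n_O - bo
        N = formula.n_C - bc
        if k < 0 or N < 0:
            continue
        if k == 0 and N != 0:
            continue
        if k > 0 and N < 2 * k:
            continue
        candidate = AcylsugarLabel(backbone, k, N)
        if label_to_formula(candidate) == formula:
            return candidate
    raise AnnotationError(
        f"{formula} is not a saturated acylsugar: no sucrose or glucose "
        "backbone reproduces its CHO stoichiometry"
    )


def adduct_mz(formula: MolecularFormula | str, adduct: str | None = "[M+H]+") -> float:
    """m/z of a singly charged adduct ion (monoisotopic, electron mass neglected).

    ``adduct=None`` returns the neutral monoisotopic mass (useful for GC-MS
    molecular ions quoted as nominal masses).
    """
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    if adduct is None:
        return formula.monoisotopic_mass
    try:
        shift = ADDUCT_SHIFTS[adduct]
    except KeyError:
        raise AnnotationError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_SHIFTS)}"
        ) from None
    return formula.monoisotopic_mass + shift


@dataclass(frozen=True)
class CalibrationSeries:
    """(alkane carbon number, retention time) pairs for the retention-index scale."""

    carbon_numbers: tuple[int, ...]
    retention_times: tuple[float, ...]

    def __post_init__(self) -> None:
        n = np.asarray(self.carbon_numbers)
        t = np.asarray(self.retention_times, dtype=float)
        if len(n) != len(t) or len(n) < 2:
            raise AnnotationError("calibration needs >= 2 (n, t) pairs of equal length")
        if not (np.diff(n) > 0).all():
            raise AnnotationError("alkane carbon numbers must be strictly increasing")
        if not (np.diff(t) > 0).all():
            raise AnnotationError("alkane retention times must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "CalibrationSeries":
        pairs = sorted(pairs)
        return cls(tuple(int(n) for n, _ in pairs), tuple(float(t) for _, t in pairs))


def kovats_index(
    rt: float,
    calibration: CalibrationSeries,
    *,
    extrapolate: bool = False,
    isothermal: bool = False,
) -> float:
    """Retention index of a peak at ``rt`` on the calibrated alkane scale.

    Default is the temperature-programmed (van den Dool-Kratz) form,
    ``100*n + 100*(rt - t_n)/(t_(n+1) - t_n)`` for the bracketing alkanes.
    ``isothermal=True`` applies the log-time Kovats form instead.  Retention
    times outside the calibrated range raise unless ``extrapolate`` is set.
    """
    ns = np.asarray(calibration.carbon_numbers, dtype=float)
    ts = np.asarray(calibration.retention_times, dtype=float)
    if not extrapolate and not (ts[0] <= rt <= ts[-1]):
        raise AnnotationError(
            f"rt={rt} outside calibration range [{ts[0]}, {ts[-1]}]; "
            "pass extrapolate=True to allow"
        )
    # bracketing segment (clamped to the end segments when extrapolating)
    i = int(np.searchsorted(ts, rt, side="right") - 1)
    i = min(max(i, 0), len(ts) - 2)
    if isothermal:
        if rt <= 0:
            raise AnnotationError("isothermal form needs rt > 0")
        frac = (math.log(rt) - math.log(ts[i])) / (math.log(ts[i + 1]) - math.log(ts[i]))
    else:
        frac = (rt - ts[i]) / (ts[i + 1] - ts[i])
    return 100.0 * (ns[i] + (ns[i + 1] - ns[i]) * frac)


def normalize_abundance(
    raw_area: float,
    internal_standard_area: float,
    dilution_factor: float = 1.0,
    fresh_weight: float = 1.0,
    *,
    dilution_divides: bool = False,
) -> float:
    """Internal-standard, dilution and fresh-weight corrected abundance.

    Default convention is ``(raw / IS) * dilution / weight``; set
    ``dilution_divides=True`` for labs whose dilution factor is recorded as a
    divisor.
    """
    if internal_standard_area <= 0:
        raise AnnotationError("internal standard area must be > 0")
    if fresh_weight <= 0:
        raise AnnotationError("fresh weight must be > 0")
    if dilution_factor <= 0:
        raise AnnotationError("dilution factor must be > 0")
    if raw_area < 0:
        raise AnnotationError("raw area must be >= 0")
    x = raw_area / internal_standard_area
    x = x / dilution_factor if dilution_divides else x * dilution_factor
    return x / fresh_weight


@dataclass
class FeatureTable:
    """Replicate-level accession x metabolite abundance table with metadata.

    ``data`` is long format with columns ``accession, replicate, feature_id,
    abundance``; ``feature_meta`` is indexed by ``feature_id`` and carries at
    least a ``feature_class`` column (``acylsugar`` or ``volatile``) plus any
    annotation columns (label, m/z, KI).
    """

    data: pd.DataFrame
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("accession", "replicate", "feature_id", "abundance")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise AnnotationError(f"feature table missing columns {missing}")
        if (self.data["abundance"] < 0).any():
            raise AnnotationError("negative abundances are not allowed")
        dup = self.data.duplicated(["accession", "replicate", "feature_id"])
        if dup.any():
            rows = self.data.loc[dup, ["accession", "replicate", "feature_id"]]
            raise AnnotationError(
                f"duplicate (accession, replicate, feature) rows:\n{rows.head()}"
            )

    @property
    def accessions(self) -> list:
        return sorted(self.data["accession"].unique())

    @property
    def feature_ids(self) -> list:
        return sorted(self.data["feature_id"].unique())

    def replicate_matrix(self) -> pd.DataFrame:
        """Wide (accession, replicate) x feature matrix, absences zero-filled."""
        wide = self.data.pivot_table(
            index=["accession", "replicate"],
            columns="feature_id",
            values="abundance",
            aggfunc="sum",
            fill_value=0.0,
        )
        return wide.sort_index(axis=0).sort_index(axis=1)

    def accession_means(self) -> pd.DataFrame:
        """Accession x feature matrix of means across biological replicates.

        This is the RF classifier's input representation.
        """
        return self.replicate_matrix().groupby(level="accession").mean()


def build_feature_table(
    measurements: pd.DataFrame,
    merge_rules: Mapping[str, Sequence[str]] | None = None,
    feature_meta: pd.DataFrame | None = None,
) -> FeatureTable:
    """Assemble a :class:`FeatureTable`, applying co-elution merge rules.

    ``merge_rules`` maps a merged feature name to the features it absorbs
    (abundances are summed per accession x replicate), e.g. co-eluting GC
    peaks reported as one:
    ``{"beta-phellandrene/D-limonene": ["beta-phellandrene", "D-limonene"]}``.
    """
    df = measurements.copy()
    if merge_rules:
        mapping: dict[str, str] = {}
        for merged, members in merge_rules.items():
            for m in members:
                if m in mapping:
                    raise AnnotationError(f"feature {m!r} appears in two merge rules")
                mapping[m] = merged
        df["feature_id"] = df["feature_id"].map(lambda f: mapping.get(f, f))
        df = (
            df.groupby(["accession", "replicate", "feature_id"], as_index=False)
            .agg({"abundance": "sum"})
        )
    meta = feature_meta if feature_meta is not None else pd.DataFrame()
    return FeatureTable(df, meta)


def assign_isomer_suffixes(features: pd.DataFrame) -> pd.Series:
    """Label structural isomers "-1, -2, ..." by retention-time order.

    ``features`` needs columns ``label`` (base annotation, e.g. "S3:15") and
    ``rt``.  Features whose label occurs once keep the bare label.
    """
    out = features["label"].astype(str).copy()
    for label, group in features.groupby("label", sort=False):
        if len(group) > 1:
            order = group.sort_values("rt", kind="mergesort").index
            for rank, idx in enumerate(order, start=1):
                out.loc[idx] = f"{label}-{rank}"
    return out
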