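"""ELISA quantification of natural-antibody (nAb) signal and total IgM.

Plasma is assayed on 96-well plates coated with bacterial cell-envelope
protein; bound IgM is read as absorbance at 450 nm. Technical replicates
are aggregated per sample, samples are compared against background wells
(BSA blank, secondary-antibody-only) with an exact rank test, specificity
is quantified as the fractional signal reduction when plasma is
pre-incubated with the soluble antigen, and total IgM is read off a
standard curve fitted to kit standards.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats as _sps

_ROWS = "ABCDEFGH"
_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")


class WellRole(str, Enum):
    SAMPLE = "sample"
    BSA_BLANK = "bsa_blank"
    SECONDARY_ONLY = "secondary_only"
    STANDARD = "standard"
    COMPETITION = "competition"


def well_to_index(well: str) -> tuple[int, int]:
    """Map a well name like ``'B7'`` to (row, col) indices into the 8x12 grid."""
    m = _WELL_RE.match(well.strip().upper())
    if not m:
        raise ValueError(f"malformed well name {well!r}")
    row = _ROWS.index(m.group(1))
    col = int(m.group(2)) - 1
    if not 0 <= col < 12:
        raise ValueError(f"well {well!r} outside the 8x12 plate")
    return row, col


@dataclass(frozen=True)
class WellInfo:
    """Layout annotation for one used well."""

    role: WellRole
    sample_id: str | None = None
    replicate: int | None = None
    concentration: float | None = None  # standards only
    paired_sample_id: str | None = None  # competition wells: the uncompeted sample


@dataclass(frozen=True)
class ElisaPlate:
    """An 8x12 grid of A450 readings plus a per-well layout.

    Only wells present in ``layout`` are considered used; every sample
    must have at least two replicate wells, and standards (when present)
    at least four distinct nominal concentrations.
    """

    wells: np.ndarray  # shape (8, 12), A450 >= 0
    layout: Mapping[str, WellInfo]

    def __post_init__(self) -> None:
        w = np.asarray(self.wells, dtype=float)
        if w.shape != (8, 12):
            raise ValueError(f"plate grid must be 8x12, got {w.shape}")
        if np.any(w < 0):
            raise ValueError("negative A450 reading on plate")
        object.__setattr__(self, "wells", w)
        for well in self.layout:
            well_to_index(well)  # validates names
        counts: dict[str, int] = {}
        for info in self.layout.values():
            if info.role in (WellRole.SAMPLE,) and info.sample_id is not None:
                counts[info.sample_id] = counts.get(info.sample_id, 0) + 1
        for sid, n in counts.items():
            if n < 2:
                raise ValueError(f"sample {sid!r} has {n} replicate well(s); need >=2")
        concs = {
            info.concentration
            for info in self.layout.values()
            if info.role is WellRole.STANDARD
        }
        if concs and len(concs) < 4:
            raise ValueError("standards must cover >=4 distinct concentrations")

    def values(self, role: WellRole, sample_id: str | None = None) -> np.ndarray:
        """A450 readings of wells with ``role`` (optionally one sample's)."""
        out = []
        for well, info in self.layout.items():
            if info.role is not role:
                continue
            if sample_id is not None and info.sample_id != sample_id:
                continue
            r, c = well_to_index(well)
            out.append(self.wells[r, c])
        return np.asarray(out, dtype=float)

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for info in self.layout.values():
            if info.role is WellRole.SAMPLE and info.sample_id:
                seen.setdefault(info.sample_id)
        return list(seen)


@dataclass(frozen=True)
class ElisaResult:
    """Aggregated per-sample ELISA readout."""

    sample_id: str
    mean_a450: float
    sd_a450: float
    se_a450: float
    n_replicates: int
    above_background: bool | None = None
    p_background: float | None = None
    competition_reduction: float | None = None
    total_igm: float | None = None


def aggregate_replicates(plate: ElisaPlate, sample_id: str) -> ElisaResult:
    """Mean, SD and SE of one sample's replicate wells (no outlier removal)."""
    vals = plate.values(WellRole.SAMPLE, sample_id)
    if vals.size == 0:
        raise KeyError(f"sample {sample_id!r} not on plate")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ElisaResult(
        sample_id=sample_id,
        mean_a450=float(np.mean(vals)),
        sd_a450=sd,
        se_a450=sd / math.sqrt(vals.size),
        n_replicates=int(vals.size),
    )


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x vs y with ties counted one half."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p-value by exhaustive enumeration.

    Enumerates all C(n+m, n) assignments of the pooled values to the two
    groups and counts assignments whose U statistic deviates from its null
    mean by at least as much as the observed one. Handles ties (each tied
    pair contributes one half to U). Intended for small groups; the number
    of assignments grows combinatorially.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    mu = n * m / 2.0
    observed = abs(_mann_whitney_u(x, y) - mu)
    total = 0
    extreme = 0
    idx = np.arange(n + m)
    for chosen in itertools.combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(chosen)] = True
        u = _mann_whitney_u(pooled[mask], pooled[~mask])
        total += 1
        # small tolerance so exact ties in U count as "at least as extreme"
        if abs(u - mu) >= observed - 1e-12:
            extreme += 1
    return extreme / total


def compare_to_background(
    sample_wells: Sequence[float],
    background_wells: Sequence[float],
    alpha: float = 0.05 / 3,
) -> tuple[float, bool]:
    """Rank-based two-group comparison of sample vs background wells.

    Uses the exact permutation null of the Mann-Whitney U statistic when
    both groups have at most 8 wells, and the normal approximation (with
    tie correction and continuity correction) otherwise. Returns the
    two-sided p-value and whether it is below ``alpha`` — by default the
    Bonferroni-corrected level for the three background comparisons.
    """
    x = np.asarray(sample_wells, dtype=float)
    y = np.asarray(background_wells, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both well sets must be non-empty")
    if x.size <= 8 and y.size <= 8:
        p = mann_whitney_exact(x, y)
    else:
        p = float(_sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return p, p < alpha


def competition_reduction(uncompeted_mean: float, competed_mean: float) -> float:
    """Fractional signal loss after antigen pre-incubation: 1 - competed/uncompeted."""
    if uncompeted_mean <= 0:
        raise ValueError("uncompeted mean must be positive")
    return 1.0 - competed_mean / uncompeted_mean


# ---------------------------------------------------------------------------
# Standard curve (total IgM)


def _four_pl(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Four-parameter logistic: asymptotes a (low-conc) and d, midpoint c, slope b."""
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted concentration-response curve for the IgM kit standards."""

    params: tuple[float, float, float, float]  # a, b, c, d of the 4PL
    od_range: tuple[float, float]  # fitted A450 span of the standards
    model: str = "4pl"  # or "linear_log" fallback
    linear_coef: tuple[float, float] | None = None  # slope, intercept on log10 conc

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        x = np.asarray(concentration, dtype=float)
        if self.model == "4pl":
            return _four_pl(x, *self.params)
        s, i = self.linear_coef  # type: ignore[misc]
        return s * np.log10(x) + i


@dataclass(frozen=True)
class Interpolation:
    concentration: float | None
    in_range: bool


def fit_standard_curve(
    standards: Sequence[tuple[float, float]],
) -> StandardCurve:
    """Least-squares 4PL fit of A450 against nominal concentration.

    Replicate readings at the same nominal concentration are averaged
    first. Falls back to a linear fit in log10 concentration if the 4PL
    optimiser fails. Standards must cover at least four distinct
    concentrations and be monotone after averaging.
    """
    by_conc: dict[float, list[float]] = {}
    for conc, od in standards:
        if conc <= 0:
            raise ValueError("standard concentrations must be positive")
        by_conc.setdefault(float(conc), []).append(float(od))
    if len(by_conc) < 4:
        raise ValueError("need >=4 distinct standard concentrations")
    concs = np.array(sorted(by_conc))
    ods = np.array([np.mean(by_conc[c]) for c in concs])
    diffs = np.diff(ods)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("standards are non-monotone after replicate averaging")

    a0 = float(ods[0]) if diffs[0] > 0 else float(ods[-1])
    d0 = float(ods[-1]) if diffs[0] > 0 else float(ods[0])
    c0 = float(np.sqrt(concs[0] * concs[-1]))
    p0 = (float(ods[0]), 1.0 if diffs[0] > 0 else -1.0, c0, float(ods[-1]))
    try:
        params, _ = optimize.curve_fit(_four_pl, concs, ods, p0=p0, maxfev=20000)
        fitted = _four_pl(concs, *params)
        if not np.all(np.isfinite(fitted)):
            raise RuntimeError("non-finite 4PL fit")
        return StandardCurve(
            params=tuple(float(p) for p in params),
            od_range=(float(np.min(fitted)), float(np.max(fitted))),
        )
    except (RuntimeError, optimize.OptimizeWarning):
        slope, intercept = np.polyfit(np.log10(concs), ods, 1)
        fitted = slope * np.log10(concs) + intercept
        return StandardCurve(
            params=(math.nan,) * 4,
            od_range=(float(np.min(fitted)), float(np.max(fitted))),
            model="linear_log",
            linear_coef=(float(slope), float(intercept)),
        )


def interpolate(curve: StandardCurve, a450: float) -> Interpolation:
    """Invert the standard curve at an observed A450.

    Queries outside the standards' fitted OD span are flagged out-of-range
    and not extrapolated.
    """
    lo, hi = curve.od_range
    if not lo <= a450 <= hi:
        return Interpolation(concentration=None, in_range=False)
    if curve.model == "4pl":
        a, b, c, d = curve.params
        # invert d + (a-d)/(1+(x/c)^b) = y
        ratio = (a - d) / (a450 - d) - 1.0
        if ratio <= 0:
            return Interpolation(concentration=None, in_range=False)
        conc = c * ratio ** (1.0 / b)
    else:
        s, i = curve.linear_coef  # type: ignore[misc]
        conc = 10.0 ** ((a450 - i) / s)
    return Interpolation(concentration=float(conc), in_range=True)
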