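"""Fixed assay constants shared across the pipeline.

The defaults encode the assay protocol: bacterial growth is read at OD600
on a microplate reader, hourly from 5 h to 14 h after inoculation (plus a
time-zero read), killing capacity is summarised as the time at which the
fitted linear growth phase crosses OD 0.3, and samples that never grow are
censored at 15 h, one hour past the end of the incubation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AssayConfig:
    """Constants of the bacterial-killing and ELISA assays.

    Attributes
    ----------
    od_threshold:
        OD600 level whose crossing time is the killing statistic
        (approximately mid-growth-curve). Default 0.3.
    censor_time_h:
        Hours assigned to samples with no detectable growth. Default 15,
        strictly past the incubation horizon.
    horizon_h:
        Length of the incubation in hours; no reads beyond it. Default 14.
    min_window:
        Minimum number of points in the linear-phase regression window.
    growth_min_rise:
        Minimum OD rise above the first read for growth to count as
        detected; also the slack allowed when checking that a curve
        approaches ``od_threshold``.
    n_controls_expected:
        Number of plasma-free control growth curves expected per run.
    bonferroni_alpha:
        Per-comparison significance level for the ELISA background tests
        (0.05 corrected for three comparisons).
    """

    od_threshold: float = 0.3
    censor_time_h: float = 15.0
    horizon_h: float = 14.0
    min_window: int = 3
    growth_min_rise: float = 0.05
    n_controls_expected: int = 4
    bonferroni_alpha: float = 0.05 / 3

    def __post_init__(self) -> None:
        if not 0.0 < self.od_threshold < 1.0:
            raise ValueError(f"od_threshold must be in (0, 1), got {self.od_threshold}")
        if not self.censor_time_h > self.horizon_h:
            raise ValueError(
                "censor_time_h must exceed horizon_h "
                f"({self.censor_time_h} <= {self.horizon_h})"
            )
        if self.min_window < 3:
            raise ValueError("min_window must be at least 3")
        if self.growth_min_rise < 0:
            raise ValueError("growth_min_rise must be non-negative")


#: Read schedule of the killing assay: one read at inoculation, then hourly
#: from 5 h through the 14 h horizon (11 points total).
DEFAULT_TIME_GRID: tuple[float, ...] = (0.0,) + tuple(float(t) for t in range(5, 15))
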