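"""Two-arm trial summary statistics from typed-in tables.

The clinical arm of the study compares combined-therapy (observation)
and monotherapy (control) groups of 40 pregnancy-induced-hypertension
patients each: categorical efficacy counts, adverse maternal/infant
outcome counts, and mean ± SD summaries of blood pressure, biochemistry
and coagulation endpoints.  This module recomputes the published rates
and the between-arm tests (Pearson chi-square for counts, t test from
summary moments) directly from those tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = ["ArmOutcomeCounts", "ArmMomentSummary", "AdverseCounts",
           "total_effective_rate", "incidence_rate", "chi_square_2x2",
           "welch_t_from_summary", "student_t_from_summary",
           "EFFICACY_TABLE", "ADVERSE_TABLE", "MOMENT_TABLES", "trial_report"]


@dataclass(frozen=True)
class ArmOutcomeCounts:
    """Efficacy-category counts for one arm."""

    markedly_effective: int
    effective: int
    ineffective: int

    def __post_init__(self) -> None:
        if min(self.markedly_effective, self.effective, self.ineffective) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.markedly_effective + self.effective + self.ineffective

    @property
    def responders(self) -> int:
        return self.markedly_effective + self.effective


@dataclass(frozen=True)
class ArmMomentSummary:
    """Mean ± SD with n for one arm of one endpoint."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class AdverseCounts:
    """Patients with >= 1 adverse outcome out of an arm of size n."""

    events: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.events <= self.n:
            raise ValueError("need 0 <= events <= n")


def total_effective_rate(c: ArmOutcomeCounts) -> float:
    """(markedly effective + effective) / cases × 100, exact to 2 decimals."""
    if c.total == 0:
        raise ValueError("empty arm")
    return float(Fraction(c.responders, c.total) * 100)


def incidence_rate(a: AdverseCounts) -> float:
    """events / n × 100, exact to 2 decimals."""
    if a.n == 0:
        raise ValueError("empty arm")
    return float(Fraction(a.events, a.n) * 100)


def chi_square_2x2(success_a: int, n_a: int, success_b: int, n_b: int,
                   correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 table, optional Yates continuity correction.

    Returns (statistic, two-sided p from chi-square with 1 df).
    Symmetric under swapping arms and under swapping success/failure.
    """
    cells = np.array([[success_a, n_a - success_a],
                      [success_b, n_b - success_b]], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    n = cells.sum()
    r = cells.sum(axis=1)
    c = cells.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("degenerate margins")
    det = cells[0, 0] * cells[1, 1] - cells[0, 1] * cells[1, 0]
    num = abs(det)
    if correction:
        num = max(num - n / 2.0, 0.0)
    statistic = n * num ** 2 / (r[0] * r[1] * c[0] * c[1])
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def welch_t_from_summary(a: ArmMomentSummary, b: ArmMomentSummary
                         ) -> tuple[float, float, float]:
    """Welch two-sample t from summary moments: (t, df, two-sided p).

    df follows Welch–Satterthwaite.  Zero variance in both arms with
    equal means gives (0, n_a + n_b − 2, 1); with unequal means it is
    degenerate and raises.
    """
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if va + vb == 0.0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def student_t_from_summary(a: ArmMomentSummary, b: ArmMomentSummary
                           ) -> tuple[float, float, float]:
    """Pooled-variance Student t from summary moments: (t, df, two-sided p)."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    denom = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if denom == 0.0:
        if a.mean == b.mean:
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (a.mean - b.mean) / denom
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


# --------------------------------------------------------------------------
# typed-in study tables (inputs to the computations above)
# --------------------------------------------------------------------------

EFFICACY_TABLE = {
    "observation": ArmOutcomeCounts(markedly_effective=23, effective=14, ineffective=3),
    "control": ArmOutcomeCounts(markedly_effective=18, effective=11, ineffective=11),
}

ADVERSE_TABLE = {
    "observation": AdverseCounts(events=3, n=40),
    "control": AdverseCounts(events=9, n=40),
}

# endpoint -> time -> arm -> mean ± SD (n = 40 throughout)
MOMENT_TABLES = {
    "SBP_mmHg": {
        "before": {"observation": ArmMomentSummary(158.32, 11.86, 40),
                   "control": ArmMomentSummary(159.33, 11.90, 40)},
        "after": {"observation": ArmMomentSummary(127.85, 9.34, 40),
                  "control": ArmMomentSummary(138.49, 9.11, 40)},
    },
    "DBP_mmHg": {
        "before": {"observation": ArmMomentSummary(117.09, 11.56, 40),
                   "control": ArmMomentSummary(119.13, 10.97, 40)},
        "after": {"observation": ArmMomentSummary(78.35, 9.77, 40),
                  "control": ArmMomentSummary(85.84, 8.71, 40)},
    },
    "urine_protein_24h_g": {
        "before": {"observation": ArmMomentSummary(4.19, 1.36, 40),
                   "control": ArmMomentSummary(4.17, 1.29, 40)},
        "after": {"observation": ArmMomentSummary(1.36, 0.24, 40),
                  "control": ArmMomentSummary(2.25, 0.26, 40)},
    },
    "ET1_mg_L": {
        "before": {"observation": ArmMomentSummary(52.41, 5.73, 40),
                   "control": ArmMomentSummary(52.97, 6.04, 40)},
        "after": {"observation": ArmMomentSummary(43.11, 4.28, 40),
                  "control": ArmMomentSummary(49.88, 5.03, 40)},
    },
    "CRP_mg_L": {
        "before": {"observation": ArmMomentSummary(16.24, 1.87, 40),
                   "control": ArmMomentSummary(16.28, 1.93, 40)},
        "after": {"observation": ArmMomentSummary(3.61, 0.54, 40),
                  "control": ArmMomentSummary(9.28, 0.93, 40)},
    },
    "Hcy_umol_L": {
        "before": {"observation": ArmMomentSummary(23.11, 2.97, 40),
                   "control": ArmMomentSummary(23.24, 3.05, 40)},
        "after": {"observation": ArmMomentSummary(12.56, 1.74, 40),
                  "control": ArmMomentSummary(19.15, 1.86, 40)},
    },
    "PT_s": {
        "before": {"observation": ArmMomentSummary(10.16, 1.01, 40),
                   "control": ArmMomentSummary(10.18, 0.89, 40)},
        "after": {"observation": ArmMomentSummary(12.98, 1.25, 40),
                  "control": ArmMomentSummary(11.01, 0.94, 40)},
    },
    "APTT_s": {
        "before": {"observation": ArmMomentSummary(21.41, 2.15, 40),
                   "control": ArmMomentSummary(21.36, 2.21, 40)},
        "after": {"observation": ArmMomentSummary(29.85, 2.43, 40),
                  "control": ArmMomentSummary(25.07, 2.11, 40)},
    },
    "TT_s": {
        "before": {"observation": ArmMomentSummary(16.12, 0.49, 40),
                   "control": ArmMomentSummary(16.16, 0.55, 40)},
        "after": {"observation": ArmMomentSummary(17.85, 0.27, 40),
                  "control": ArmMomentSummary(16.86, 0.28, 40)},
    },
    "FIB_g_L": {
        "before": {"observation": ArmMomentSummary(5.06, 0.46, 40),
                   "control": ArmMomentSummary(5.04, 0.47, 40)},
        "after": {"observation": ArmMomentSummary(3.12, 0.52, 40),
                  "control": ArmMomentSummary(4.32, 0.64, 40)},
    },
}


def trial_report(efficacy: dict | None = None, adverse: dict | None = None,
                 moments: dict | None = None, correction: bool = False) -> dict:
    """Full recomputation of the trial tables into a JSON-serializable dict."""
    efficacy = efficacy or EFFICACY_TABLE
    adverse = adverse or ADVERSE_TABLE
    moments = moments or MOMENT_TABLES

    obs, ctl = efficacy["observation"], efficacy["control"]
    chi, p_chi = chi_square_2x2(obs.responders, obs.total,
                                ctl.responders, ctl.total, correction=correction)
    adv_o, adv_c = adverse["observation"], adverse["control"]
    chi_adv, p_adv = chi_square_2x2(adv_o.events, adv_o.n,
                                    adv_c.events, adv_c.n, correction=correction)
    report = {
        "total_effective_rate": {
            "observation_pct": total_effective_rate(obs),
            "control_pct": total_effective_rate(ctl),
            "chi_square": chi, "p": p_chi,
        },
        "adverse_incidence": {
            "observation_pct": incidence_rate(adv_o),
            "control_pct": incidence_rate(adv_c),
            "chi_square": chi_adv, "p": p_adv,
        },
        "endpoints": {},
    }
    for name, times in moments.items():
        report["endpoints"][name] = {}
        for when, arms in times.items():
            t, df, p = welch_t_from_summary(arms["observation"], arms["control"])
            report["endpoints"][name][when] = {
                "observation": [arms["observation"].mean, arms["observation"].sd],
                "control": [arms["control"].mean, arms["control"].sd],
                "welch_t": t, "df": df, "p": p,
            }
    return report
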