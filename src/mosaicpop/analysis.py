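"""Cross-cutting analysis of fitted design results.

Pools the per-cell estimates of equilibrium size K and return time phi
across landscape variants and perturbation intensities: the K–phi
correlation per species, detection of incomplete recovery (declining
per-segment asymptotes under repeated perturbation), and deltas of K and
phi between consecutive landscape variants.  Only converged perturbed
fits contribute phi; unperturbed cells contribute K only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "correlate_K_phi",
    "recovery_decline_test",
    "DeclineVerdict",
    "compare_variants",
]


def correlate_K_phi(results: pd.DataFrame, species: str):
    """Pearson correlation of K and phi for one species across design cells.

    ``results`` is a long-format table with columns species, variant,
    intensity, K, phi, converged.  Uses converged perturbed fits only.
    Returns (r, two-sided p, n); with fewer than 3 pairs raises, and with
    zero variance in either K or phi returns (nan, nan, n) — an undefined
    marker, not a number.
    """
    sub = results[
        (results["species"] == species)
        & results["converged"]
        & (results["intensity"] > 0)
        & results["phi"].notna()
        & results["K"].notna()
    ]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 (K, phi) pairs for {species}, got {n}")
    K = sub["K"].to_numpy(float)
    phi = sub["phi"].to_numpy(float)
    if np.ptp(K) < 1e-12 or np.ptp(phi) < 1e-12:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(K, phi)
    return float(r), float(p), n


@dataclass
class DeclineVerdict:
    slope: float
    slope_ci: tuple
    incomplete_recovery: bool
    n_segments: int


def recovery_decline_test(segment_Ks: pd.DataFrame, ci_level: float = 0.95) -> DeclineVerdict:
    """Weighted linear trend of per-segment asymptotes on segment index.

    ``segment_Ks`` needs columns segment, K, se_K (as returned by
    :func:`mosaicpop.recovery.segmentwise_K`).  Weights are inverse
    squared standard errors.  ``incomplete_recovery`` is flagged when the
    slope confidence interval lies entirely below zero.
    """
    if len(segment_Ks) < 3:
        raise ValueError("need >= 3 segments for a trend test")
    x = sm.add_constant(segment_Ks["segment"].to_numpy(float))
    w = 1.0 / np.clip(segment_Ks["se_K"].to_numpy(float), 1e-12, None) ** 2
    res = sm.WLS(segment_Ks["K"].to_numpy(float), x, weights=w).fit()
    lo, hi = res.conf_int(alpha=1.0 - ci_level)[1]
    return DeclineVerdict(
        slope=float(res.params[1]),
        slope_ci=(float(lo), float(hi)),
        incomplete_recovery=bool(hi < 0.0),
        n_segments=len(segment_Ks),
    )


def _se_from_ci(lo: float, hi: float) -> float:
    return (hi - lo) / (2.0 * 1.959963984540054)


def compare_variants(results: pd.DataFrame) -> pd.DataFrame:
    """Signed K and phi differences between consecutive landscape variants.

    For every species x intensity, computes delta = value(next) −
    value(previous) over the transitions A→B, B→C, C→D, with normal-
    approximation confidence intervals propagated from the per-fit
    bootstrap intervals.  Transitions with a missing or unconverged side
    are omitted (with a notice column rather than an error).
    """
    order = ["A", "B", "C", "D"]
    rows = []
    for (sp, inten), sub in results.groupby(["species", "intensity"], sort=True):
        sub = sub.set_index("variant")
        for a, b in zip(order[:-1], order[1:]):
            if a not in sub.index or b not in sub.index:
                continue
            ra, rb = sub.loc[a], sub.loc[b]
            if not (ra.get("converged", False) and rb.get("converged", False)):
                rows.append(
                    {"species": sp, "intensity": inten, "transition": f"{a}->{b}",
                     "dK": np.nan, "dK_ci_lo": np.nan, "dK_ci_hi": np.nan,
                     "dphi": np.nan, "dphi_ci_lo": np.nan, "dphi_ci_hi": np.nan,
                     "notice": "unconverged fit on one side"}
                )
                continue
            rec = {"species": sp, "intensity": inten, "transition": f"{a}->{b}", "notice": ""}
            rec["dK"] = float(rb["K"] - ra["K"])
            if all(pd.notna([ra.get("K_lo"), ra.get("K_hi"), rb.get("K_lo"), rb.get("K_hi")])):
                se = math_hypot(_se_from_ci(ra["K_lo"], ra["K_hi"]), _se_from_ci(rb["K_lo"], rb["K_hi"]))
                rec["dK_ci_lo"], rec["dK_ci_hi"] = rec["dK"] - 1.96 * se, rec["dK"] + 1.96 * se
            else:
                rec["dK_ci_lo"] = rec["dK_ci_hi"] = np.nan
            if pd.notna(ra.get("phi")) and pd.notna(rb.get("phi")):
                rec["dphi"] = float(rb["phi"] - ra["phi"])
                if all(pd.notna([ra.get("phi_lo"), ra.get("phi_hi"), rb.get("phi_lo"), rb.get("phi_hi")])):
                    se = math_hypot(
                        _se_from_ci(ra["phi_lo"], ra["phi_hi"]), _se_from_ci(rb["phi_lo"], rb["phi_hi"])
                    )
                    rec["dphi_ci_lo"], rec["dphi_ci_hi"] = rec["dphi"] - 1.96 * se, rec["dphi"] + 1.96 * se
                else:
                    rec["dphi_ci_lo"] = rec["dphi_ci_hi"] = np.nan
            else:
                rec["dphi"] = rec["dphi_ci_lo"] = rec["dphi_ci_hi"] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def math_hypot(a: float, b: float) -> float:
    return float(np.hypot(a, b))
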