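"""Kaplan–Meier estimation and log-rank screening of candidate genes.

Patients are dichotomized at an expression quantile (median by default,
ties to the low group) and the two arms compared with the standard
unweighted log-rank test; a gene is flagged prognostic when the test's
p-value falls below the screening threshold (0.01 by default). Curve
estimation and the test statistic are delegated to lifelines; this module
owns the screening logic, the split rule and the direction call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import ParameterError, ValidationError
from .io import SurvivalTable

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Stepwise product-limit survival estimate.

    ``times`` are the distinct observed times in ascending order;
    ``survival`` the value of S(t) just after each time; ``at_risk`` the
    size of the risk set just before it. S(0) = 1 and S is non-increasing;
    deaths are processed before censorings at tied times.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): the step value at the latest event time ≤ t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def area(self, upto: float) -> float:
        """∫₀^upto S(t) dt — restricted mean survival time."""
        grid = np.concatenate(([0.0], self.times[self.times < upto], [upto]))
        heights = np.array([self.at(t) for t in grid[:-1]])
        return float(np.sum(heights * np.diff(grid)))


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator for right-censored data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("need at least one subject")
    if (times <= 0).any():
        raise ValidationError("times must be strictly positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    # drop the t=0 row lifelines prepends; keep observed times only
    tbl = tbl[tbl.index > 0]
    sf = kmf.survival_function_["KM_estimate"]
    surv = np.array([float(sf.loc[t]) for t in tbl.index])
    return KMCurve(
        times=tbl.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(dtype=int),
    )


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Unweighted two-group log-rank test: (chi-square, p-value), 1 df."""
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if len(np.asarray(times_a)) == 0 or len(np.asarray(times_b)) == 0:
        raise ValidationError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValidationError("log-rank statistic undefined with zero events")
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def survival_screen(
    genes: list[str],
    surv: SurvivalTable,
    split_quantile: float = 0.5,
    p_thresh: float = 0.01,
) -> pd.DataFrame:
    """Log-rank screen of each gene's high- vs low-expression arm.

    Per gene: patients with expression ≤ the split quantile form the low
    group (ties go low), the rest the high group. Splits that leave an arm
    empty (e.g. constant expression) skip the gene with a warning.
    Direction is ``high-worse`` when the high arm's KM curve has the
    smaller area up to the last observed event time.

    Returns a DataFrame indexed by gene with columns split, chi_square,
    p_value, prognostic, direction.
    """
    if not 0.0 < split_quantile < 1.0:
        raise ParameterError("split_quantile must be in (0,1)")
    missing = [g for g in genes if g not in surv.gene_ids]
    if missing:
        raise ValidationError(f"genes absent from survival table: {missing[:5]}")
    times, events = surv.times, surv.events
    last_event = times[events == 1].max() if (events == 1).any() else times.max()
    rows = {}
    for gene in genes:
        expr = surv.data[gene].to_numpy(dtype=float)
        cut = float(np.quantile(expr, split_quantile))
        low = expr <= cut
        high = ~low
        if not low.any() or not high.any():
            logger.warning("gene %s: degenerate split at quantile %.2f; skipped",
                           gene, split_quantile)
            continue
        if events[low].sum() + events[high].sum() == 0:
            logger.warning("gene %s: no events in either arm; skipped", gene)
            continue
        chi2, p = logrank(times[high], events[high], times[low], events[low])
        km_high = km_estimate(times[high], events[high])
        km_low = km_estimate(times[low], events[low])
        direction = (
            "high-worse"
            if km_high.area(last_event) < km_low.area(last_event)
            else "high-better"
        )
        rows[gene] = {
            "split": cut,
            "chi_square": chi2,
            "p_value": p,
            "prognostic": p < p_thresh,
            "direction": direction,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out
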