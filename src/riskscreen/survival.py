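"""Kaplan–Meier estimation and two-group log-rank screening.

The product-limit estimator and the log-rank statistic are implemented from
first principles (they are the computation this stage exists to provide, and
established survival packages serve as independent cross-checks in the test
suite).  Genes are screened by dichotomizing patients at an expression cutoff
(median by default) and testing high vs low with the log-rank test.

Conventions: at tied times, events precede censorings (standard product-limit
convention); ``high`` means expression strictly above the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import SurvivalRecord

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(t)=1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def median_survival(self) -> float:
        """Smallest event time with S(t) <= 0.5; inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("inf")


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    n_high: int
    n_low: int


@dataclass
class GeneSurvivalScreen:
    gene: str
    endpoint: str
    cutoff_method: str
    cutoff_value: float
    logrank: LogRankResult
    alpha: float

    @property
    def significant(self) -> bool:
        return self.logrank.p_value < self.alpha


def _times_events(records: list[SurvivalRecord]):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimator(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    S(t_k) = prod_{j<=k} (1 − d_j/n_j) over distinct event times t_j with d_j
    events and n_j subjects at risk just before t_j.  A subject censored at
    exactly an event time is still at risk for that event (events first).
    """
    if not records:
        raise ValueError("no survival records")
    time, event = _times_events(records)
    event_times = np.unique(time[event == 1])

    n = time.size
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    for k, t in enumerate(event_times):
        at_risk[k] = int(np.sum(time >= t))
        n_events[k] = int(np.sum((time == t) & (event == 1)))
    survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(event_times=event_times, survival=survival,
                   at_risk=at_risk, n_events=n_events)


def logrank_test(high: list[SurvivalRecord],
                 low: list[SurvivalRecord]) -> LogRankResult:
    """Two-group log-rank test: observed vs hypergeometric-expected events at
    each distinct event time; statistic (O−E)²/V, p from chi²(1 df)."""
    if not high or not low:
        raise ValueError("both groups must be non-empty")
    t1, e1 = _times_events(high)
    t2, e2 = _times_events(low)
    time = np.concatenate([t1, t2])
    event = np.concatenate([e1, e2])
    in_high = np.concatenate([np.ones(t1.size, bool), np.zeros(t2.size, bool)])

    if event.sum() == 0:
        raise ValueError("no events in either group")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_high).sum())
        died = (time == t) & (event == 1)
        d = int(died.sum())
        d1 = int((died & in_high).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    if var == 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
        p = max(p, float(np.finfo(float).tiny))
    return LogRankResult(chi_square=float(chi2), p_value=float(p),
                         n_high=len(high), n_low=len(low))


def dichotomize_by_expression(records: list[SurvivalRecord], gene: str,
                              method: str = "median"):
    """Split records at an expression cutoff: high = value > cutoff.

    ``method`` is ``"median"`` or ``"quantile:q"`` with q in (0, 1).
    Returns (high, low, cutoff_value).
    """
    values = []
    for r in records:
        if gene not in r.expression:
            raise KeyError(f"gene {gene!r} missing for patient {r.patient_id}")
        values.append(r.expression[gene])
    values = np.asarray(values, float)
    if np.all(values == values[0]):
        raise ValueError(f"degenerate split: constant expression for {gene!r}")

    if method == "median":
        cutoff = float(np.median(values))
    elif method.startswith("quantile:"):
        q = float(method.split(":", 1)[1])
        if not 0 < q < 1:
            raise ValueError("quantile must lie in (0, 1)")
        cutoff = float(np.quantile(values, q))
    else:
        raise ValueError(f"unknown cutoff method {method!r}")

    high = [r for r, v in zip(records, values) if v > cutoff]
    low = [r for r, v in zip(records, values) if v <= cutoff]
    if not high or not low:
        raise ValueError(f"degenerate split for {gene!r} at cutoff {cutoff}")
    return high, low, cutoff


# quantile-scan: KM-plotter-style "best cutoff" over this range; the minimum
# p over scanned cutoffs is optimistic and is flagged as such in the log
_SCAN_QUANTILES = np.round(np.arange(0.25, 0.751, 0.05), 2)


def screen_survival(genes: list[str], records: list[SurvivalRecord],
                    endpoint: str = "OS", alpha: float = 0.05,
                    cutoff: str = "median") -> list[GeneSurvivalScreen]:
    """Log-rank screen of each gene at the configured expression cutoff.

    ``cutoff="scan"`` scans quantiles 0.25–0.75 and keeps the minimum p
    (optimistic; logged warning).  No multiple-testing correction across
    genes — significance is raw p < alpha.
    """
    if endpoint not in ("OS", "RFS"):
        raise ValueError("endpoint must be 'OS' or 'RFS'")
    if cutoff == "scan":
        logger.warning("quantile-scan cutoff: scanned p-values are optimistic")

    out = []
    for gene in genes:
        if cutoff == "median":
            high, low, cut = dichotomize_by_expression(records, gene, "median")
            result = logrank_test(high, low)
        elif cutoff == "scan":
            best = None
            cut = np.nan
            for q in _SCAN_QUANTILES:
                try:
                    high, low, c = dichotomize_by_expression(
                        records, gene, f"quantile:{q}")
                    r = logrank_test(high, low)
                except ValueError:
                    continue
                if best is None or r.p_value < best.p_value:
                    best, cut = r, c
            if best is None:
                raise ValueError(f"no valid split found for {gene!r}")
            result = best
        else:
            raise ValueError(f"unknown cutoff {cutoff!r}")
        out.append(GeneSurvivalScreen(gene=gene, endpoint=endpoint,
                                      cutoff_method=cutoff, cutoff_value=cut,
                                      logrank=result, alpha=alpha))
    return out
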