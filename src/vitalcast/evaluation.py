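"""Leave-one-instance-out evaluation of the local forecaster.

Every prediction instance is held out in turn; all remaining instances (from
any patient) form the training pool of a kNN-LS-SVM fitted per target
(vital × statistic × horizon — each a separate scalar regression).  The
comparison baseline is the NaiveMean persistence rule: predict the future
window's mean as the mean of the most recently observed one-hour window.
Errors are summarised as absolute error and MAPE; predicted and actual mean
values are additionally mapped to EWS component scores, whose absolute
difference ∈ {0,1,2,3} is histogrammed; model-vs-naive absolute errors are
compared by a two-sided paired t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .ews import SCOREABLE, EwsTable, load_zol_table, score_component
from .features import (FEATURE_CHANNELS, FEATURE_NAMES, N_FEATURES_PER_CHANNEL,
                       PredictionInstance, TARGET_STATS, TARGET_VITALS)
from .lssvm import Hyperparams, TrainingPool, fit_ls_svm, knn_select

logger = logging.getLogger(__name__)

#: index of the window-B mean feature for each channel, in the x-vector
_B_MEAN_INDEX = {
    ch: 77 + FEATURE_CHANNELS.index(ch) * N_FEATURES_PER_CHANNEL
    + FEATURE_NAMES.index("mean")
    for ch in FEATURE_CHANNELS
}


def naive_predict_mean(instance: PredictionInstance, vital: str) -> float:
    """NaiveMean persistence: the previous hour's (window B) observed mean is
    the prediction of every future window's mean."""
    if vital not in _B_MEAN_INDEX:
        raise KeyError(f"channel {vital!r} not featurized")
    return float(instance.x[_B_MEAN_INDEX[vital]])


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, 100·mean(|y−ŷ|/|y|); zero-valued
    truths are excluded from the mean with a logged count."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    nz = y_true != 0
    n_excluded = int((~nz).sum())
    if n_excluded:
        logger.warning("mape: excluded %d zero-valued truths", n_excluded)
    if not nz.any():
        raise ValueError("all truths are zero; MAPE undefined")
    return float(100.0 * np.mean(np.abs(y_true[nz] - y_pred[nz])
                                 / np.abs(y_true[nz])))


def ews_error_histogram(errors) -> np.ndarray:
    """Normalized histogram of integer EWS-component errors over {0,1,2,3}."""
    e = np.asarray(errors)
    if e.size == 0:
        raise ValueError("empty error array")
    if not np.isin(e, (0, 1, 2, 3)).all():
        raise ValueError("EWS errors must be integers in {0,1,2,3}")
    counts = np.bincount(e.astype(int), minlength=4)[:4]
    return counts / counts.sum()


def paired_ttest_report(ae_model, ae_naive, alpha: float = 0.01
                        ) -> tuple[float, float, bool]:
    """Two-sided paired t-test on per-instance absolute-error differences.

    All-zero differences give (t=0, p=1) exactly; zero-variance nonzero
    differences are degenerate (t=±inf, p=0).
    """
    a = np.asarray(ae_model, dtype=float)
    b = np.asarray(ae_naive, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length arrays of at least 2 pairs")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0, False
        t = math.copysign(math.inf, d[0])
        logger.warning("degenerate paired t-test: constant nonzero differences")
        return t, 0.0, True
    res = sstats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


@dataclass
class PredictionRecord:
    """One LOIO prediction of one target."""

    instance_id: str
    vital: str
    statistic: str
    horizon: int
    y_true: float
    y_model: float
    y_naive: float | None = None          # NaiveMean, mean statistic only
    ews_true: int | None = None
    ews_model: int | None = None
    ews_naive: int | None = None


def loio_evaluate(instances: list[PredictionInstance],
                  hp: Hyperparams,
                  vitals=TARGET_VITALS,
                  statistics=("mean",),
                  horizons=(1,),
                  audit_leakage: bool = True) -> list[PredictionRecord]:
    """Leave-one-instance-out predictions for every requested target.

    For each held-out instance the pool is all remaining instances; the
    neighbour selection is shared across targets (the feature vector does not
    depend on the target).  The held-out instance is audited to never appear
    in its own neighbourhood.
    """
    n = len(instances)
    if n < hp.k + 1:
        raise ValueError(
            f"need at least k+1={hp.k + 1} instances for LOIO, got {n}")
    X = np.vstack([inst.x for inst in instances])
    targets = [(v, s, h) for v in vitals for s in statistics for h in horizons]
    records: list[PredictionRecord] = []
    keep = np.ones(n, dtype=bool)
    for i, inst in enumerate(instances):
        keep[i] = False
        pool_ids = np.flatnonzero(keep)
        pool_X = X[pool_ids]
        avail = [t for t in targets if t in inst.targets]
        if avail:
            # neighbour search once per held-out instance
            geom_pool = TrainingPool(pool_X, np.zeros(len(pool_ids)))
            sel = knn_select(inst.x, geom_pool, hp.k, hp.metric)
            neigh_global = pool_ids[sel.indices]
            if audit_leakage and i in neigh_global:
                raise AssertionError(
                    "LOIO violation: held-out instance in its own neighbourhood")
            sigma0 = hp.resolve_sigma0(X.shape[1])
            Xn = geom_pool.standardize(pool_X[sel.indices])
            xq = geom_pool.standardize(inst.x)
        for vital, stat, h in avail:
            yn = np.array([instances[j].targets.get((vital, stat, h), np.nan)
                           for j in neigh_global])
            ok = np.isfinite(yn)
            model = fit_ls_svm(Xn[ok], yn[ok], hp.gamma, sigma0)
            y_model = float(model.predict(xq)[0])
            y_naive = naive_predict_mean(inst, vital) if stat == "mean" else None
            records.append(PredictionRecord(
                instance_id=f"{inst.patient_id}@{inst.t_end}",
                vital=vital, statistic=stat, horizon=h,
                y_true=inst.targets[(vital, stat, h)],
                y_model=y_model, y_naive=y_naive))
        keep[i] = True
    return records


def ews_error_records(records: list[PredictionRecord],
                      table: EwsTable | None = None,
                      statistic: str = "mean") -> list[PredictionRecord]:
    """Attach EWS component scores to mean-statistic records of scoreable
    vitals (HR, SBP, SpO2, RR); pulse pressure has no EWS row and is rejected."""
    if table is None:
        table = load_zol_table()
    out = []
    for r in records:
        if r.statistic != statistic:
            continue
        if r.vital == "pp":
            raise ValueError("pulse pressure is not an EWS vital")
        if r.vital not in SCOREABLE:
            raise ValueError(f"{r.vital!r} is not a scoreable vital")
        vital_name = SCOREABLE[r.vital]
        r.ews_true = score_component(vital_name, r.y_true, table)
        r.ews_model = score_component(vital_name, r.y_model, table)
        if r.y_naive is not None:
            r.ews_naive = score_component(vital_name, r.y_naive, table)
        out.append(r)
    return out


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class EvaluationReport:
    """Aggregate LOIO evaluation summaries."""

    abs_error: dict[tuple[str, str, int], np.ndarray]
    mape: dict[tuple[str, str, int], float]
    ews_hist_model: dict[str, np.ndarray]
    ews_hist_naive: dict[str, np.ndarray]
    ttests: dict[tuple[str, int], tuple[float, float, bool]]
    alpha: float
    n_records: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_records": self.n_records,
            "mape": {f"{v}_{s}_h{h}": m for (v, s, h), m in self.mape.items()},
            "abs_error_mean": {f"{v}_{s}_h{h}": float(np.mean(a))
                               for (v, s, h), a in self.abs_error.items()},
            "ews_hist_model": {v: list(map(float, hgram))
                               for v, hgram in self.ews_hist_model.items()},
            "ews_hist_naive": {v: list(map(float, hgram))
                               for v, hgram in self.ews_hist_naive.items()},
            "paired_ttests": {f"{v}_h{h}": {"t": t, "p": p, "significant": sig}
                              for (v, h), (t, p, sig) in self.ttests.items()},
        }


def summarize(records: list[PredictionRecord],
              table: EwsTable | None = None,
              alpha: float = 0.01) -> EvaluationReport:
    """Build the full report from LOIO records: per-target absolute-error
    arrays and MAPE, per-vital EWS-error histograms (model and naive, mean
    statistic), and per-(vital, horizon) paired t-tests model vs naive."""
    if table is None:
        table = load_zol_table()
    abs_error: dict = {}
    mape_d: dict = {}
    by_target: dict = {}
    for r in records:
        by_target.setdefault((r.vital, r.statistic, r.horizon), []).append(r)
    for key, rs in by_target.items():
        yt = np.array([r.y_true for r in rs])
        ym = np.array([r.y_model for r in rs])
        abs_error[key] = np.abs(yt - ym)
        mape_d[key] = mape(yt, ym)

    ews_recs = ews_error_records(
        [r for r in records if r.statistic == "mean" and r.vital in SCOREABLE],
        table)
    hist_m: dict = {}
    hist_n: dict = {}
    for vital in sorted({r.vital for r in ews_recs}):
        rs = [r for r in ews_recs if r.vital == vital]
        hist_m[vital] = ews_error_histogram(
            [abs(r.ews_model - r.ews_true) for r in rs])
        withnaive = [r for r in rs if r.ews_naive is not None]
        if withnaive:
            hist_n[vital] = ews_error_histogram(
                [abs(r.ews_naive - r.ews_true) for r in withnaive])

    ttests: dict = {}
    for (vital, stat, h), rs in by_target.items():
        if stat != "mean":
            continue
        paired = [r for r in rs if r.y_naive is not None]
        if len(paired) < 2:
            continue
        ae_m = [abs(r.y_model - r.y_true) for r in paired]
        ae_n = [abs(r.y_naive - r.y_true) for r in paired]
        ttests[(vital, h)] = paired_ttest_report(ae_m, ae_n, alpha)

    return EvaluationReport(abs_error=abs_error, mape=mape_d,
                            ews_hist_model=hist_m, ews_hist_naive=hist_n,
                            ttests=ttests, alpha=alpha, n_records=len(records))
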