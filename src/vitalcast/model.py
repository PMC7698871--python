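"""Model/Results interface over the forecasting pipeline.

:class:`VitalForecastModel` is constructed from prediction instances (or
straight from recordings / a wide instance DataFrame), holds the evaluation
protocol configuration, and ``fit()`` runs the leave-one-instance-out
evaluation, returning a :class:`VitalForecastResults` that carries the
per-target error arrays, MAPE table, EWS-error histograms and paired
t-tests, with ``summary()`` and plotting helpers.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import evaluation as ev
from .conditioning import FilterSpec, denoise_recording
from .ews import EwsTable, load_zol_table
from .features import (DEFAULT_HORIZONS, TARGET_STATS, TARGET_VITALS,
                       enumerate_instances, frame_to_instances)
from .lssvm import Hyperparams

logger = logging.getLogger(__name__)

#: per-ward protocol: neighbourhood size and prediction horizons
PROFILE_DEFAULTS = {
    "cardiology": {"k": 25, "horizons": (1, 2, 3)},
    "postsurgical": {"k": 25, "horizons": (1, 2, 3)},
    "dialysis": {"k": 15, "horizons": (1,)},
}


class VitalForecastModel:
    """kNN-LS-SVM forecaster of windowed vital-sign statistics.

    Parameters
    ----------
    instances
        Prediction instances (70-min history → future-window targets).
    profile
        Ward profile; sets the default neighbourhood size (25, or 15 for
        dialysis) and horizons ({1,2,3}, or {1} for dialysis).
    hyperparams
        Overrides the profile default entirely when given.
    vitals, statistics, horizons
        The targets evaluated; default all five vitals, the mean statistic,
        and the profile's horizons.
    """

    def __init__(self, instances, profile: str = "cardiology",
                 hyperparams: Hyperparams | None = None,
                 vitals=TARGET_VITALS, statistics=("mean",),
                 horizons=None, ews_table: EwsTable | None = None,
                 alpha: float = 0.01):
        if profile not in PROFILE_DEFAULTS:
            raise ValueError(f"unknown profile {profile!r}")
        defaults = PROFILE_DEFAULTS[profile]
        self.instances = list(instances)
        self.profile = profile
        self.hyperparams = hyperparams or Hyperparams(k=defaults["k"])
        self.vitals = tuple(vitals)
        self.statistics = tuple(statistics)
        self.horizons = tuple(horizons) if horizons is not None else defaults["horizons"]
        self.ews_table = ews_table or load_zol_table()
        self.alpha = alpha

    @classmethod
    def from_recordings(cls, recordings, profile: str = "cardiology",
                        denoise: bool = True,
                        filter_spec: FilterSpec | None = None,
                        step_min: int = 10, **kwargs) -> "VitalForecastModel":
        """Featurize denoised recordings and construct the model."""
        horizons = kwargs.get("horizons") or PROFILE_DEFAULTS[profile]["horizons"]
        instances = []
        for rec in recordings:
            r = denoise_recording(rec, filter_spec) if denoise else rec
            instances.extend(enumerate_instances(r, step_min=step_min,
                                                 horizons=horizons))
        return cls(instances, profile=profile, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "VitalForecastModel":
        """Construct from the wide instance table written by ``featurize``."""
        return cls(frame_to_instances(df), **kwargs)

    def fit(self) -> "VitalForecastResults":
        """Run the leave-one-instance-out evaluation over the pool."""
        records = ev.loio_evaluate(
            self.instances, self.hyperparams,
            vitals=self.vitals, statistics=self.statistics,
            horizons=self.horizons)
        report = ev.summarize(records, table=self.ews_table, alpha=self.alpha)
        return VitalForecastResults(self, records, report)


class VitalForecastResults:
    """LOIO evaluation results: errors, MAPE, EWS histograms, t-tests."""

    def __init__(self, model: VitalForecastModel, records, report):
        self.model = model
        self.records = records
        self.report = report

    @property
    def records_frame(self) -> pd.DataFrame:
        return ev.records_to_frame(self.records)

    def mape_table(self) -> pd.DataFrame:
        rows = [{"vital": v, "statistic": s, "horizon_h": h, "mape_pct": m}
                for (v, s, h), m in sorted(self.report.mape.items())]
        return pd.DataFrame(rows)

    def abs_error(self, vital: str, statistic: str = "mean",
                  horizon: int = 1) -> np.ndarray:
        return self.report.abs_error[(vital, statistic, horizon)]

    def ews_histogram(self, vital: str, predictor: str = "model") -> np.ndarray:
        src = (self.report.ews_hist_model if predictor == "model"
               else self.report.ews_hist_naive)
        return src[vital]

    def ttest(self, vital: str, horizon: int = 1):
        return self.report.ttests[(vital, horizon)]

    def summary(self) -> str:
        rep = self.report
        lines = []
        hp = self.model.hyperparams
        lines.append("kNN-LS-SVM vital-sign forecast — leave-one-instance-out")
        lines.append("=" * 62)
        lines.append(f"profile: {self.model.profile}   instances: "
                     f"{len(self.model.instances)}   records: {rep.n_records}")
        lines.append(f"k={hp.k}  gamma={hp.gamma:g}  "
                     f"sigma0={'sqrt(d)' if hp.sigma0 is None else f'{hp.sigma0:g}'}"
                     f"  metric={hp.metric}")
        lines.append("-" * 62)
        lines.append(f"{'target':<22}{'MAE':>9}{'MAPE %':>9}")
        for (v, s, h), m in sorted(rep.mape.items()):
            mae = float(np.mean(rep.abs_error[(v, s, h)]))
            lines.append(f"{v + ' ' + s + ' +' + str(h) + 'h':<22}"
                         f"{mae:>9.3f}{m:>9.2f}")
        if rep.ttests:
            lines.append("-" * 62)
            lines.append(f"{'paired t (|e| model vs naive)':<32}"
                         f"{'t':>9}{'p':>12}{'sig':>6}")
            for (v, h), (t, p, sig) in sorted(rep.ttests.items()):
                lines.append(f"{v + ' mean +' + str(h) + 'h':<32}"
                             f"{t:>9.3f}{p:>12.3g}"
                             f"{'*' if sig else '':>6}")
            lines.append(f"(two-sided, alpha={rep.alpha})")
        if rep.ews_hist_model:
            lines.append("-" * 62)
            lines.append("EWS-component absolute-error histograms "
                         "(mass on error 0/1/2/3)")
            for v, hg in sorted(rep.ews_hist_model.items()):
                hn = rep.ews_hist_naive.get(v)
                m = "/".join(f"{x:.2f}" for x in hg)
                nv = "/".join(f"{x:.2f}" for x in hn) if hn is not None else "-"
                lines.append(f"  {v:<6} model {m}   naive {nv}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.report.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def plot_abs_error_boxplots(self, vital: str, ax=None):
        """Box plots of absolute error per horizon, naive alongside model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rep = self.report
        data, labels = [], []
        df = self.records_frame
        sub = df[(df.vital == vital) & (df.statistic == "mean")
                 & df.y_naive.notna()]
        if len(sub):
            data.append(np.abs(sub.y_naive - sub.y_true))
            labels.append("naive +1h")
        for (v, s, h), ae in sorted(rep.abs_error.items()):
            if v == vital:
                data.append(ae)
                labels.append(f"{s} +{h}h")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("absolute error")
        ax.set_title(f"{vital} — LOIO absolute error")
        return ax

    def plot_ews_histograms(self, vital: str, ax=None):
        """Side-by-side normalized EWS-error histograms, model vs naive."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        w = 0.35
        xs = np.arange(4)
        ax.bar(xs - w / 2, self.report.ews_hist_model[vital], w, label="model")
        if vital in self.report.ews_hist_naive:
            ax.bar(xs + w / 2, self.report.ews_hist_naive[vital], w,
                   label="naive")
        ax.set_xticks(xs)
        ax.set_xlabel("EWS component absolute error")
        ax.set_ylabel("normalized frequency")
        ax.set_title(vital)
        ax.legend()
        return ax
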