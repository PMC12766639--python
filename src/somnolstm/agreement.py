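"""Device-vs-PSG performance evaluation.

Implements the standardised agreement framework used for wearable sleep
trackers: discrepancy analysis of night-level summary measures (signed
difference and mean absolute error, at the individual and group level),
epoch-by-epoch confusion metrics (accuracy; sensitivity = correctly
classified sleep epochs; specificity = correctly classified wake epochs;
one-vs-rest per stage for the staged task) and Bland-Altman bias / 95%
limits of agreement with explicit assumption tests:

1. proportional bias — OLS slope t-test of the differences on the pair means;
2. heteroscedasticity — OLS slope t-test of |residuals| on the pair means;
3. normality of the differences — D'Agostino-Pearson omnibus test.

Under the constant-bias model, bias = mean(d) and LOA = bias +/- 1.96*SD(d).
When proportional bias is flagged, bias(m) = b0 + b1*m and
LOA(m) = bias(m) +/- 1.96*SD(residuals). Metrics with empty denominators are
reported as missing (NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ValidationError
from .metrics import SleepSummary

#: z-quantile used for the 95% limits of agreement.
LOA_Z = 1.96
#: Below this many pairs the Bland-Altman assumption tests are unreliable.
MIN_BA_PAIRS = 8


@dataclass
class ConfusionMatrix:
    """Square (reference x predicted) count table over a fixed class order."""

    counts: np.ndarray
    classes: tuple[str, ...]
    participant_id: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(pred, ref, classes: tuple[str, ...], participant_id: str = "") -> ConfusionMatrix:
    """Count (reference, predicted) pairs."""
    pred = np.asarray(pred, dtype=object)
    ref = np.asarray(ref, dtype=object)
    if len(pred) != len(ref):
        raise ValidationError("pred/ref length mismatch")
    bad = (set(pred) | set(ref)) - set(classes)
    if bad:
        raise ValidationError(f"labels outside class alphabet: {sorted(bad)}")
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(ref, pred):
        counts[idx[r], idx[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes),
                           participant_id=participant_id)


@dataclass
class EBEMetrics:
    """Epoch-by-epoch metrics, in percent. NaN marks empty denominators."""

    accuracy: float
    sensitivity: float
    specificity: float
    per_stage: dict[str, dict[str, float]] = field(default_factory=dict)
    participant_id: str = ""

    def as_dict(self) -> dict[str, float]:
        out = {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
               "specificity": self.specificity}
        for stage, m in self.per_stage.items():
            for name, v in m.items():
                out[f"{stage}_{name}"] = v
        return out


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def ebe_metrics(cm: ConfusionMatrix, positive_class: str = "sleep") -> EBEMetrics:
    """Accuracy/sensitivity/specificity from a confusion matrix.

    Binary: sensitivity is the proportion of reference-sleep epochs
    classified sleep; specificity the proportion of reference-wake epochs
    classified wake. For the staged task each stage is scored one-vs-rest
    and the headline sensitivity/specificity use sleep = any non-wake stage.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    counts = cm.counts
    classes = cm.classes
    acc = _ratio(np.trace(counts), cm.total)
    if len(classes) == 2:
        pi = classes.index(positive_class)
        ni = 1 - pi
        sens = _ratio(counts[pi, pi], counts[pi].sum())
        spec = _ratio(counts[ni, ni], counts[ni].sum())
        return EBEMetrics(acc, sens, spec, participant_id=cm.participant_id)
    # staged task: headline sens/spec collapse to wake vs not-wake
    wi = classes.index("wake")
    sleep_mask = np.arange(len(classes)) != wi
    sens = _ratio(counts[sleep_mask][:, sleep_mask].sum(), counts[sleep_mask].sum())
    spec = _ratio(counts[wi, wi], counts[wi].sum())
    per_stage = {}
    for i, c in enumerate(classes):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = cm.total - tp - fn - fp
        per_stage[c] = {
            "accuracy": _ratio(tp + tn, cm.total),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
        }
    return EBEMetrics(acc, sens, spec, per_stage=per_stage,
                      participant_id=cm.participant_id)


def group_ebe(per_participant: list[EBEMetrics]) -> pd.DataFrame:
    """Unweighted group mean and sample SD of individual-level metrics.

    Missing (NaN) individual values are excluded metric-wise; the returned
    table carries the contributing count per metric.
    """
    if not per_participant:
        raise ValidationError("need at least one participant")
    rows = pd.DataFrame([m.as_dict() for m in per_participant])
    return pd.DataFrame({
        "mean": rows.mean(skipna=True),
        "sd": rows.std(ddof=1, skipna=True),
        "n": rows.notna().sum(),
    })


@dataclass
class DiscrepancyRecord:
    """Per-participant device - PSG differences of the summary measures."""

    participant_id: str
    signed: dict[str, float]
    absolute: dict[str, float]


def discrepancy(device: SleepSummary, psg: SleepSummary) -> DiscrepancyRecord:
    if device.epoch_len_s != psg.epoch_len_s:
        raise ValidationError("summaries use different epoch lengths")
    dd, pp = device.as_dict(), psg.as_dict()
    signed = {m: dd[m] - pp[m] for m in pp if m in dd}
    return DiscrepancyRecord(
        participant_id=psg.participant_id or device.participant_id,
        signed=signed,
        absolute={m: abs(v) for m, v in signed.items()},
    )


def group_discrepancy(records: list[DiscrepancyRecord]) -> pd.DataFrame:
    """Group MAE (mean of individual absolute errors) and mean signed bias."""
    if not records:
        raise ValidationError("need at least one record")
    signed = pd.DataFrame([r.signed for r in records])
    return pd.DataFrame({
        "mae": signed.abs().mean(),
        "bias": signed.mean(),
        "sd_signed": signed.std(ddof=1),
        "n": signed.notna().sum(),
    })


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement with assumption flags.

    With proportional bias flagged, ``bias_intercept``/``bias_slope`` define
    bias(m) = b0 + b1*m and ``loa_halfwidth`` the residual-based half-width;
    the scalar ``bias``/``loa_lower``/``loa_upper`` always report the
    constant-bias model for reference.
    """

    n: int
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    proportional_bias: bool
    heteroscedastic: bool
    non_normal: bool
    assumptions_unreliable: bool
    degenerate: bool
    bias_intercept: float | None = None
    bias_slope: float | None = None
    loa_halfwidth: float | None = None
    p_slope: float = float("nan")
    p_hetero: float = float("nan")
    p_normal: float = float("nan")

    def summary(self) -> str:
        lines = [
            "Bland-Altman agreement",
            f"  n pairs          : {self.n}",
            f"  bias             : {self.bias:.4f}",
            f"  95% LOA          : [{self.loa_lower:.4f}, {self.loa_upper:.4f}]",
            f"  proportional bias: {self.proportional_bias} (p={self.p_slope:.4g})",
            f"  heteroscedastic  : {self.heteroscedastic} (p={self.p_hetero:.4g})",
            f"  non-normal diffs : {self.non_normal} (p={self.p_normal:.4g})",
        ]
        if self.proportional_bias and self.bias_slope is not None:
            lines.append(
                f"  bias(m)          : {self.bias_intercept:.4f} + "
                f"{self.bias_slope:.4f}*m +/- {LOA_Z}*{self.loa_halfwidth / LOA_Z:.4f}"
            )
        if self.assumptions_unreliable:
            lines.append(f"  note: fewer than {MIN_BA_PAIRS} pairs; "
                         "assumption tests unreliable")
        return "\n".join(lines)


def bland_altman(device_values, psg_values, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman analysis of paired night-level measures."""
    dev = np.asarray(device_values, dtype=float)
    psg = np.asarray(psg_values, dtype=float)
    if dev.shape != psg.shape or dev.ndim != 1:
        raise ValidationError("device/psg must be 1-d arrays of equal length")
    ok = np.isfinite(dev) & np.isfinite(psg)
    dev, psg = dev[ok], psg[ok]
    n = len(dev)
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    d = dev - psg
    m = (dev + psg) / 2.0

    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    lo, hi = bias - LOA_Z * sd, bias + LOA_Z * sd

    unreliable = n < MIN_BA_PAIRS
    prop = het = nonnorm = False
    p_slope = p_het = p_norm = float("nan")
    b0 = b1 = halfwidth = None
    if not degenerate and np.ptp(m) > 0:
        X = sm.add_constant(m)
        fit = sm.OLS(d, X).fit()
        p_slope = float(fit.pvalues[1])
        prop = p_slope < alpha
        resid = fit.resid
        fit_h = sm.OLS(np.abs(resid), X).fit()
        p_het = float(fit_h.pvalues[1])
        het = p_het < alpha
        if n >= MIN_BA_PAIRS:
            p_norm = float(stats.normaltest(d).pvalue)
            nonnorm = p_norm < alpha
        if prop:
            b0, b1 = float(fit.params[0]), float(fit.params[1])
            halfwidth = float(LOA_Z * resid.std(ddof=1))
    return BlandAltmanResult(
        n=n, bias=bias, loa_lower=lo, loa_upper=hi, sd_diff=sd,
        proportional_bias=prop, heteroscedastic=het, non_normal=nonnorm,
        assumptions_unreliable=unreliable, degenerate=degenerate,
        bias_intercept=b0, bias_slope=b1, loa_halfwidth=halfwidth,
        p_slope=p_slope, p_hetero=p_het, p_normal=p_norm,
    )
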