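"""Performance indices for gait-phase detectors.

Detector output is scored against the FSR reference along four axes:

* **Timing errors** — signed differences (ms) between each detected phase
  onset and its nearest reference onset of the same phase (negative =
  anticipation), matched greedily one-to-one within half a mean stride.
* **Tolerance-windowed sensitivity / specificity** — a reference sample of
  phase p counts as a true positive when any prediction within a 60 ms
  window centered on it carries p; a non-p reference sample counts as a
  true negative unless the whole window is predicted p.  A constant
  single-phase prediction over four equal phases therefore scores ~25 %
  sensitivity and ~75 % specificity, the chance floor of this metric.
* **Goodness index** — G = sqrt((1-TPR)^2 + (1-TNR)^2), the Euclidean
  distance from the perfect corner of ROC space: optimum <= 0.25, good
  below 0.7, random at 0.7 (~= sqrt(2)/2), bad above.
* **Variability** — mean time (MT) and coefficient of variation
  CoV = 100 * std / MT of stride and per-phase durations.
* **ICC(A,1)** — single-measurement absolute-agreement two-way ICC for
  inter-rater reliability of MT/CoV across classifiers.

The confusion matrix is computed sample-wise *without* the tolerance
window (it describes raw per-sample confusion); TPR/TNR use the window.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .fsr import phase_onsets
from .phases import GaitPhase, LabelSequence, N_PHASES, PHASE_NAMES

TOLERANCE_MS = 60.0
OPTIMUM_G = 0.25
RANDOM_G = 0.70


def goodness(tpr: float, tnr: float) -> float:
    """Goodness index: distance from the perfect classifier in ROC space."""
    if not (0.0 <= tpr <= 1.0 and 0.0 <= tnr <= 1.0):
        raise ValueError("TPR and TNR must lie in [0, 1]")
    return math.hypot(1.0 - tpr, 1.0 - tnr)


def goodness_band(g: float) -> str:
    """Qualitative band: optimum <= 0.25 < good < 0.7 = random < bad."""
    if g <= OPTIMUM_G:
        return "optimum"
    # chance level: G = sqrt(1/2) ~= 0.7 (the printed band boundary)
    if math.isclose(g, math.sqrt(0.5), abs_tol=5e-3) or math.isclose(g, RANDOM_G, abs_tol=1e-9):
        return "random"
    if g < RANDOM_G:
        return "good"
    return "bad"


@dataclass
class TimingErrorReport:
    """Signed onset timing errors per phase (ms; negative = anticipation)."""

    errors_ms: dict          # phase name -> array of matched signed errors
    misses: dict             # phase name -> count of unmatched reference onsets
    extras: dict             # phase name -> count of unmatched predicted onsets

    def mean_ms(self, phase: str) -> float:
        e = self.errors_ms[phase]
        return float(np.mean(e)) if len(e) else float("nan")

    def std_ms(self, phase: str) -> float:
        e = self.errors_ms[phase]
        return float(np.std(e, ddof=1)) if len(e) > 1 else float("nan")

    def mean_abs_ms(self, phase: str) -> float:
        e = self.errors_ms[phase]
        return float(np.mean(np.abs(e))) if len(e) else float("nan")

    def summary(self) -> str:
        lines = ["Timing errors vs reference (mean +/- std, ms)"]
        for p in PHASE_NAMES:
            lines.append(f"  {p}: {self.mean_ms(p):7.1f} +/- {self.std_ms(p):5.1f} "
                         f"(n={len(self.errors_ms[p])}, missed {self.misses[p]})")
        return "\n".join(lines)


def timing_errors(
    pred: LabelSequence,
    ref: LabelSequence,
    max_match_ms: float | None = None,
) -> TimingErrorReport:
    """Match detected phase onsets to reference onsets and report errors.

    Greedy nearest-neighbor matching, one-to-one, within
    ``max_match_ms`` (default: half the mean reference stride), so a
    single detected onset cannot absorb several reference events.
    """
    if pred.fs != ref.fs:
        raise ValueError("prediction and reference must share a sampling rate")
    ref_on = phase_onsets(ref)
    pred_on = phase_onsets(pred)
    if max_match_ms is None:
        hs = ref_on[GaitPhase.HS]
        max_match_ms = (500.0 * float(np.mean(np.diff(hs)))
                        if hs.size >= 2 else 500.0)
    errors, misses, extras = {}, {}, {}
    for phase in GaitPhase:
        r = ref_on[phase]
        p = pred_on[phase]
        pairs = [(abs(tp - tr) * 1e3, i, j) for i, tr in enumerate(r)
                 for j, tp in enumerate(p) if abs(tp - tr) * 1e3 <= max_match_ms]
        pairs.sort()
        used_r: set[int] = set()
        used_p: set[int] = set()
        errs = {}
        for _, i, j in pairs:
            if i in used_r or j in used_p:
                continue
            used_r.add(i)
            used_p.add(j)
            errs[i] = (p[j] - r[i]) * 1e3
        errors[phase.name] = np.array([errs[i] for i in sorted(errs)])
        misses[phase.name] = len(r) - len(used_r)
        extras[phase.name] = len(p) - len(used_p)
    return TimingErrorReport(errors, misses, extras)


@dataclass
class ClassifierScore:
    """Tolerance-windowed per-phase rates, goodness and confusion matrix."""

    tpr: dict                # phase name -> float
    tnr: dict
    g: dict                  # per-phase goodness
    macro_tpr: float
    macro_tnr: float
    macro_g: float           # goodness of the phase-averaged rates
    confusion_pct: np.ndarray  # (4, 4) row-normalized percent, no tolerance
    accuracy_pct: float

    def summary(self) -> str:
        lines = ["Phase   TPR     TNR     G"]
        for p in PHASE_NAMES:
            lines.append(f"  {p}  {self.tpr[p]:6.3f}  {self.tnr[p]:6.3f}  {self.g[p]:6.3f}")
        lines.append(f"  macro {self.macro_tpr:6.3f}  {self.macro_tnr:6.3f}  "
                     f"{self.macro_g:6.3f} ({goodness_band(self.macro_g)})")
        lines.append(f"  overall accuracy {self.accuracy_pct:.2f}%")
        return "\n".join(lines)


def sample_metrics(
    pred: LabelSequence,
    ref: LabelSequence,
    tolerance_ms: float = TOLERANCE_MS,
) -> ClassifierScore:
    """Sample-wise classification scores with a tolerance window.

    The window spans ``tolerance_ms`` centered on each reference sample
    (+-30 ms by default, ~6 samples at 200 Hz).  With ``tolerance_ms=0``
    the scores reduce to exact per-sample agreement.
    """
    if len(pred) != len(ref) or pred.fs != ref.fs:
        raise ValueError("prediction and reference must share length and rate")
    half = int(round(tolerance_ms / 2.0 / 1000.0 * ref.fs))
    size = 2 * half + 1
    p_lab, r_lab = pred.labels, ref.labels
    tpr, tnr, g = {}, {}, {}
    for phase in GaitPhase:
        is_p = (p_lab == int(phase))
        ref_p = (r_lab == int(phase))
        if half > 0:
            any_p = maximum_filter1d(is_p.astype(np.uint8), size=size).astype(bool)
            all_p = minimum_filter1d(is_p.astype(np.uint8), size=size).astype(bool)
        else:
            any_p = all_p = is_p
        tp = int(np.sum(ref_p & any_p))
        fn = int(np.sum(ref_p & ~any_p))
        tn = int(np.sum(~ref_p & ~all_p))
        fp = int(np.sum(~ref_p & all_p))
        tpr[phase.name] = tp / (tp + fn) if tp + fn else float("nan")
        tnr[phase.name] = tn / (tn + fp) if tn + fp else float("nan")
        g[phase.name] = goodness(tpr[phase.name], tnr[phase.name])
    macro_tpr = float(np.mean([tpr[p] for p in PHASE_NAMES]))
    macro_tnr = float(np.mean([tnr[p] for p in PHASE_NAMES]))
    # sample-wise confusion without tolerance, row-normalized to percent
    conf = np.zeros((N_PHASES, N_PHASES))
    for i in range(N_PHASES):
        sel = r_lab == i
        n = int(np.sum(sel))
        if n:
            conf[i] = np.bincount(p_lab[sel], minlength=N_PHASES) / n * 100.0
    acc = float(np.mean(p_lab == r_lab) * 100.0)
    return ClassifierScore(tpr=tpr, tnr=tnr, g=g, macro_tpr=macro_tpr,
                           macro_tnr=macro_tnr,
                           macro_g=goodness(macro_tpr, macro_tnr),
                           confusion_pct=conf, accuracy_pct=acc)


@dataclass
class VariabilityReport:
    """Mean time and coefficient of variation of stride and phase durations."""

    mt_ms: dict              # 'stride' and phase names -> mean duration, ms
    std_ms: dict
    cov_pct: dict            # 100 * std / MT

    def summary(self) -> str:
        lines = ["        MT (ms)   std    CoV (%)"]
        for k in ("stride",) + PHASE_NAMES:
            lines.append(f"  {k:7s} {self.mt_ms[k]:7.1f} {self.std_ms[k]:6.1f} "
                         f"{self.cov_pct[k]:6.2f}")
        return "\n".join(lines)


def mt_cov(labels: LabelSequence) -> VariabilityReport:
    """Stride and per-phase duration statistics.

    Strides run HS onset to HS onset; incomplete leading/trailing strides
    are dropped.  Standard deviations use the sample (n-1) convention —
    stride counts per trial are small.
    """
    lab = labels.labels
    t = labels.t
    change = np.flatnonzero(np.diff(lab)) + 1
    hs_idx = change[lab[change] == int(GaitPhase.HS)]
    if hs_idx.size < 3:
        raise ValueError("need at least 2 complete strides (3 HS onsets)")
    stride_ms = np.diff(t[hs_idx]) * 1e3
    phase_ms = {p.name: [] for p in GaitPhase}
    # phase occurrences inside complete strides only
    lo, hi = hs_idx[0], hs_idx[-1]
    runs_start = np.concatenate(([0], change))
    runs_stop = np.concatenate((change, [lab.size]))
    for a, b in zip(runs_start, runs_stop):
        if a < lo or b > hi:
            continue
        phase_ms[GaitPhase(lab[a]).name].append((t[b - 1] - t[a] + 1.0 / labels.fs) * 1e3)
    mt, std, cov = {}, {}, {}
    for key, vals in [("stride", stride_ms)] + [(p, np.asarray(phase_ms[p]))
                                                for p in PHASE_NAMES]:
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            mt[key] = std[key] = cov[key] = float("nan")
            continue
        mt[key] = float(np.mean(vals))
        std[key] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        cov[key] = 100.0 * std[key] / mt[key] if mt[key] > 0 else float("nan")
    return VariabilityReport(mt_ms=mt, std_ms=std, cov_pct=cov)


def icc_a1(data: np.ndarray) -> tuple[float, str]:
    """ICC(A,1): single-measurement absolute-agreement two-way ICC.

    From the two-way ANOVA mean squares of an (n subjects x k raters)
    matrix with no missing cells::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    Returns the coefficient and its reliability band (poor < 0.4 <= fair
    < 0.6 <= good < 0.75 <= excellent).  A matrix with zero total
    variance is degenerate and returns 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("matrix must have no missing cells")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0.0:
        return 1.0, "excellent"
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    if icc < 0.4:
        band = "poor"
    elif icc < 0.6:
        band = "fair"
    elif icc < 0.75:
        band = "good"
    else:
        band = "excellent"
    return float(icc), band
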