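"""Scoring and statistics for load-estimation experiments.

Covers the validation toolchain: conversion of mixed force/moment
estimates into comparable force vectors via lever arms, Euclidean and
percentage load errors, one-vs-all multiclass ROC with macro/micro
averaging and common-threshold sensitivity/specificity/accuracy,
conditional-probability (CP) mechanoregulation curves, the correct
classification rate (CCR) they induce, and SED error distributions by
remodelling region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .images import FORMATION, QUIESCENCE, RESORPTION, RemodelingMap

__all__ = [
    "ForceVector",
    "ROCResult",
    "CPCurves",
    "to_force_vector",
    "load_error",
    "multiclass_roc",
    "cp_curves",
    "ccr",
    "max_ccr",
    "sed_error_by_region",
]

_EVENTS = (RESORPTION, QUIESCENCE, FORMATION)
_EVENT_NAMES = {RESORPTION: "resorption", QUIESCENCE: "quiescence", FORMATION: "formation"}


@dataclass(frozen=True)
class ForceVector:
    """A six-component load expressed entirely as forces (N).

    Moments are converted to equivalent torque forces through their lever
    arms so that mixed force/moment loads become comparable in one
    Euclidean space: bending moments (BX, BY) divide by half the stack
    height, the axial torsion moment (MZ) by half the dorsal length of
    the minimal bounding box.
    """

    values: tuple[float, float, float, float, float, float]
    lever_bending: float  # mm
    lever_torsion: float  # mm

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)


def to_force_vector(alpha, geometry) -> ForceVector:
    """Convert per-direction magnitudes (C, SX, SY in N; MZ, BX, BY in
    Nmm) into a pure force vector.

    ``geometry`` is the bone bounding box as (x, y, z) extents in mm;
    the bending lever arm is half the axial (z) extent, the torsion
    lever arm half the dorsal (y) extent.
    """
    a = np.asarray(alpha, dtype=np.float64)
    if a.shape != (6,):
        raise ValueError(f"expected 6 magnitudes, got shape {a.shape}")
    g = np.asarray(geometry, dtype=np.float64)
    if g.shape != (3,) or np.any(g <= 0):
        raise ValueError("geometry must be three positive bounding-box extents (mm)")
    lever_b = g[2] / 2.0
    lever_t = g[1] / 2.0
    out = a.copy()
    out[3] /= lever_t  # torsion MZ
    out[4] /= lever_b  # bending BX
    out[5] /= lever_b  # bending BY
    return ForceVector(tuple(out), lever_bending=lever_b, lever_torsion=lever_t)


def load_error(estimated: ForceVector, applied: ForceVector) -> tuple[float, float]:
    """Euclidean distance (N) and percentage error between two loads.

    The percentage error divides the 6-D Euclidean distance by the
    magnitude of the applied load; undefined (raises) for a zero applied
    load."""
    e = estimated.as_array()
    a = applied.as_array()
    dist = float(np.linalg.norm(e - a))
    mag = float(np.linalg.norm(a))
    if mag == 0:
        raise ValueError("percentage error undefined for a zero applied load")
    return dist, 100.0 * dist / mag


@dataclass
class ROCResult:
    """One-vs-all multiclass ROC with macro/micro averages.

    ``curves`` maps class name -> (fpr, tpr, thresholds); ``auc`` maps
    class name -> area under that curve.  The common threshold is the
    Youden-J optimum of the macro-averaged curve, at which sensitivity,
    specificity and (pooled) accuracy are reported.
    """

    classes: tuple[str, ...]
    curves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    auc: dict[str, float]
    macro_auc: float
    micro_auc: float
    common_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float


def multiclass_roc(scores: np.ndarray, labels: np.ndarray,
                   classes: tuple[str, ...] | None = None) -> ROCResult:
    """One-vs-all ROC over a score matrix.

    ``scores[i, j]`` is the score of sample i for class j (higher =
    more likely; e.g. the negative Euclidean distance to the canonical
    load vector of class j) and ``labels[i]`` the true class index.
    Per-class curves are swept over thresholds with trapezoidal AUC; the
    macro average is the unweighted mean of per-class AUCs, the micro
    average pools all (score, binary label) pairs and is therefore
    prevalence weighted.  Scores of different classes must live on a
    common scale for the pooled micro average and the common threshold
    to be meaningful.
    """
    S = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if S.ndim != 2:
        raise ValueError("scores must be a (n_samples, n_classes) matrix")
    n, k = S.shape
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("ROC undefined with a single class present")
    if classes is None:
        classes = tuple(str(j) for j in range(k))

    curves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    aucs: dict[str, float] = {}
    for j, name in enumerate(classes):
        bin_y = (y == j).astype(int)
        if bin_y.min() == bin_y.max():
            continue  # class absent (or universal): no curve
        fpr, tpr, thr = _roc_curve(bin_y, S[:, j])
        curves[name] = (fpr, tpr, thr)
        aucs[name] = float(_auc(fpr, tpr))
    macro = float(np.mean(list(aucs.values())))

    pooled_y = np.concatenate([(y == j).astype(int) for j in range(k)])
    pooled_s = np.concatenate([S[:, j] for j in range(k)])
    fpr_mi, tpr_mi, _ = _roc_curve(pooled_y, pooled_s)
    micro = float(_auc(fpr_mi, tpr_mi))

    # Common threshold: Youden J on the macro-averaged curve, evaluated on
    # the shared score scale.
    thresholds = np.unique(pooled_s)
    tprs = np.zeros((len(aucs), thresholds.size))
    fprs = np.zeros_like(tprs)
    row = 0
    for j, name in enumerate(classes):
        if name not in aucs:
            continue
        pos = S[y == j, j]
        neg = S[y != j, j]
        tprs[row] = (pos[:, None] >= thresholds[None, :]).mean(axis=0)
        fprs[row] = (neg[:, None] >= thresholds[None, :]).mean(axis=0)
        row += 1
    macro_tpr = tprs.mean(axis=0)
    macro_fpr = fprs.mean(axis=0)
    best = int(np.argmax(macro_tpr - macro_fpr))
    tau = float(thresholds[best])

    decisions = S >= tau
    truth = np.zeros_like(decisions, dtype=bool)
    truth[np.arange(n), y] = True
    tp = np.count_nonzero(decisions & truth)
    tn = np.count_nonzero(~decisions & ~truth)
    fp = np.count_nonzero(decisions & ~truth)
    fn = np.count_nonzero(~decisions & truth)
    return ROCResult(
        classes=tuple(classes),
        curves=curves,
        auc=aucs,
        macro_auc=macro,
        micro_auc=micro,
        common_threshold=tau,
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
        accuracy=(tp + tn) / max(tp + tn + fp + fn, 1),
    )


@dataclass
class CPCurves:
    """Conditional remodelling probabilities over normalised SED bins.

    The SED signal is normalised by its 99th percentile, clipped to
    [0, 1] and binned at 1% steps.  ``counts[e, b]`` is the raw voxel
    count of event e in bin b.  Group-wise normalisation first gives
    every event's histogram unit mass (equalising class priors), then
    bin-wise normalisation rescales each non-empty bin to sum to one
    across events — ``cp[e, b]`` is the conditional probability of
    event e given bin b under equalised priors.
    """

    counts: np.ndarray  # (3, n_bins) raw counts, event order (R, Q, F)
    cp: np.ndarray  # (3, n_bins); NaN columns for empty bins
    norm: float  # 99th-percentile normalisation value, MPa
    n_bins: int = 100

    @property
    def events(self) -> tuple[int, ...]:
        return _EVENTS

    def bin_of(self, sed) -> np.ndarray:
        x = np.clip(np.asarray(sed, dtype=np.float64) / self.norm, 0.0, 1.0)
        return np.minimum((x * self.n_bins).astype(int), self.n_bins - 1)


def cp_curves(sed: np.ndarray, labels: np.ndarray, n_bins: int = 100,
              norm: float | None = None) -> CPCurves:
    """Conditional-probability curves of remodelling events vs SED level.

    ``sed`` holds the per-surface-voxel mechanical signal (MPa) and
    ``labels`` the observed events (1/2/3).  ``norm`` overrides the 99th
    percentile normalisation (pass a group-level value for group-wise
    normalisation across datasets).  Missing event classes produce a
    partial-curve warning, not an error.
    """
    sed = np.asarray(sed, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if sed.shape != labels.shape:
        raise ValueError("sed and labels differ in length")
    if norm is None:
        norm = float(np.percentile(sed, 99))
    if not norm > 0:
        raise ValueError("normalisation percentile must be positive")
    missing = [_EVENT_NAMES[e] for e in _EVENTS if not np.any(labels == e)]
    if missing:
        warnings.warn(f"no voxels for event(s) {missing}: partial CP curves", stacklevel=2)

    x = np.clip(sed / norm, 0.0, 1.0)
    bins = np.minimum((x * n_bins).astype(int), n_bins - 1)
    counts = np.zeros((3, n_bins))
    for row, e in enumerate(_EVENTS):
        counts[row] = np.bincount(bins[labels == e], minlength=n_bins)

    # Group-wise: unit mass per event; bin-wise: unit sum per bin.
    gw = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300)
    colsum = gw.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cp = np.where(colsum > 0, gw / colsum, np.nan)
    return CPCurves(counts=counts, cp=cp, norm=norm, n_bins=n_bins)


def _predict_from_cp(cp: CPCurves, sed: np.ndarray) -> np.ndarray:
    """Argmax-CP event prediction per voxel; voxels in empty bins use the
    nearest non-empty bin."""
    bins = cp.bin_of(sed)
    nonempty = np.flatnonzero(cp.counts.sum(axis=0) > 0)
    if nonempty.size == 0:
        raise ValueError("CP curves are empty")
    # Map every bin to its nearest non-empty neighbour.
    remap = nonempty[np.argmin(np.abs(np.arange(cp.n_bins)[:, None] - nonempty[None, :]), axis=1)]
    bins = remap[bins]
    pred_rows = np.nanargmax(cp.cp[:, bins], axis=0)
    return np.asarray(_EVENTS)[pred_rows]


def ccr(cp: CPCurves, sed: np.ndarray, labels: np.ndarray) -> float:
    """Correct classification rate of remodelling events from CP curves.

    Every surface voxel is predicted as the event with maximal
    conditional probability in its SED bin; the CCR is the fraction of
    voxels whose prediction matches the observed event.  Under the
    group-wise prior equalisation, chance level is 1/3.
    """
    sed = np.asarray(sed, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    pred = _predict_from_cp(cp, sed)
    return float(np.mean(pred == labels))


def max_ccr(sed: np.ndarray, labels: np.ndarray, n_grid: int = 100) -> float:
    """Maximum CCR over ternary-threshold classifiers.

    Scans pairs of thresholds (t_r < t_f) on the normalised signal,
    predicting resorption below t_r, formation above t_f and quiescence
    between, and returns the best balanced (prior-equalised) CCR.
    Emitted alongside the argmax-CP CCR for comparability with
    threshold-based mechanoregulation summaries.
    """
    sed = np.asarray(sed, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    norm = float(np.percentile(sed, 99))
    if norm <= 0:
        raise ValueError("signal percentile must be positive")
    x = np.clip(sed / norm, 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, n_grid + 1)
    # Per-class cumulative histograms over the grid.
    cum = np.zeros((3, n_grid + 1))
    for row, e in enumerate(_EVENTS):
        hist = np.histogram(x[labels == e], bins=n_grid, range=(0.0, 1.0))[0]
        cum[row, 1:] = np.cumsum(hist)
    tot = np.maximum(cum[:, -1], 1e-300)
    frac = cum / tot[:, None]  # fraction of each class below each edge
    best = 0.0
    for i in range(n_grid + 1):  # t_r edge
        # resorption recall below t_r; quiescence within; formation above
        rec_r = frac[0, i]
        rec_q = frac[1, i:] - frac[1, i]
        rec_f = 1.0 - frac[2, i:]
        score = (rec_r + rec_q + rec_f) / 3.0
        best = max(best, float(score.max()))
    return best


def plot_cp_curves(cp: CPCurves, ax=None, path: str | None = None):
    """Render CP curves (probability of each event vs normalised SED).

    Requires matplotlib (the optional ``plot`` extra); returns the axes.
    With ``path`` the figure is also written to disk (PNG/SVG by
    extension)."""
    import matplotlib

    if ax is None and path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    x = (np.arange(cp.n_bins) + 0.5) / cp.n_bins * 100.0
    colors = {"resorption": "tab:purple", "quiescence": "tab:gray", "formation": "tab:orange"}
    for row, e in enumerate(_EVENTS):
        name = _EVENT_NAMES[e]
        ax.plot(x, cp.cp[row], label=name, color=colors[name])
    ax.set_xlabel("SED (% of 99th percentile)")
    ax.set_ylabel("conditional probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def sed_error_by_region(
    estimated_sed: np.ndarray,
    reference_sed: np.ndarray,
    labels: RemodelingMap | np.ndarray,
    voxels: np.ndarray | None = None,
    truncate_percentile: float = 98.0,
) -> dict[str, dict]:
    """Voxelwise SED error grouped by remodelling region.

    Subtracts the reference SED distribution (e.g. the field of an
    experimentally applied load) from the estimated one and groups the
    per-voxel errors by formation/quiescence/resorption.  Returns, per
    region, the error sample truncated at the given percentile of |error|
    (for histogram reporting) and the untruncated mean absolute error.
    """
    if isinstance(labels, RemodelingMap):
        voxels = labels.voxels
        lab = labels.labels
    else:
        lab = np.asarray(labels)
    est = np.asarray(estimated_sed, dtype=np.float64)
    ref = np.asarray(reference_sed, dtype=np.float64)
    if est.shape != ref.shape:
        raise ValueError("estimated and reference fields are not aligned")
    if voxels is not None:
        idx = tuple(np.asarray(voxels).T)
        err = est[idx] - ref[idx]
    else:
        if est.ravel().shape != lab.ravel().shape:
            raise ValueError("fields and labels are not aligned")
        err = (est - ref).ravel()
        lab = lab.ravel()

    out: dict[str, dict] = {}
    for e in _EVENTS:
        sel = err[lab == e]
        name = _EVENT_NAMES[e]
        if sel.size == 0:
            out[name] = {"errors": np.array([]), "mae": np.nan, "n": 0}
            continue
        cut = np.percentile(np.abs(sel), truncate_percentile)
        out[name] = {
            "errors": sel[np.abs(sel) <= cut],
            "mae": float(np.mean(np.abs(sel))),
            "n": int(sel.size),
        }
    return out
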