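"""Digital count (NanoString-style) normalization and synthetic counts.

A digital counting assay reports, per lane, raw molecule counts for
endogenous probes alongside three classes of internal controls: negative
probes (no target; estimate nonspecific background), positive spike-in
probes (fixed-input controls for lane-to-lane technical scale) and
housekeeping probes (biological content normalizers).  The pipeline here is
the standard vendor-convention workflow:

1. **Background threshold** per lane = mean + 2 x sample SD (ddof=1) of the
   lane's negative probes; endogenous and housekeeping counts are
   background-subtracted and clamped at 0.
2. **Positive-control scaling**: each lane is multiplied by
   ``mean_over_lanes(geomean of positives) / this lane's geomean of
   positives`` (arithmetic mean across lanes by convention; a geometric
   combine is exposed as an option).
3. **Housekeeping scaling**: the same geometric-mean factor computed on the
   housekeeping probes of the already-scaled matrix.

Zeros are floored at 1 inside geometric means only, keeping control
geomeans finite without discarding lanes; all other zeros are preserved.

A seeded negative-binomial generator (:func:`simulate_counts`) produces
matrices with known lane scale factors and condition fold changes so the
pipeline's fold-change recovery can be validated end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizationReport",
    "background_threshold",
    "normalize_counts",
    "simulate_counts",
    "fold_change",
]

PROBE_CLASSES = ("endogenous", "negative", "positive", "housekeeping")


@dataclass(frozen=True)
class CountMatrix:
    """Probe x lane raw counts with probe-class and lane-condition labels.

    ``counts`` is a DataFrame (probes as rows, lanes as columns) of
    non-negative integers; ``probe_class`` maps each probe to one of
    ``endogenous/negative/positive/housekeeping``; ``lane_condition`` maps
    each lane to an experimental condition label.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    lane_condition: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.probe_class.index.equals(c.index):
            raise ValueError("probe_class index must match counts rows")
        if not self.lane_condition.index.equals(c.columns):
            raise ValueError("lane_condition index must match counts columns")
        bad = set(self.probe_class) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe class(es): {sorted(bad)}")
        n_neg = int((self.probe_class == "negative").sum())
        if n_neg < 2:
            raise ValueError(f"need >= 2 negative probes, got {n_neg}")

    def probes_of(self, cls: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]

    def require_controls(self) -> None:
        """Full pipeline additionally needs >= 1 positive and >= 1 housekeeping probe."""
        for cls in ("positive", "housekeeping"):
            if len(self.probes_of(cls)) < 1:
                raise ValueError(f"need >= 1 {cls} probe for normalization")


@dataclass(frozen=True)
class NormalizationReport:
    """Output of :func:`normalize_counts`.

    ``background_threshold``, ``positive_factor`` and ``housekeeping_factor``
    are per-lane Series; ``normalized`` is the probe x lane matrix after
    background subtraction and both scalings (non-negative reals).
    """

    background_threshold: pd.Series
    positive_factor: pd.Series
    housekeeping_factor: pd.Series
    normalized: pd.DataFrame
    lane_condition: pd.Series


def background_threshold(matrix: CountMatrix) -> pd.Series:
    """Per-lane background threshold: mean + 2 x sample SD of the lane's
    negative probes (ddof=1; threshold equals the mean when all negatives
    are identical)."""
    neg = matrix.counts.loc[matrix.probes_of("negative")]
    if len(neg) < 2:
        raise ValueError(f"need >= 2 negative probes, got {len(neg)}")
    return neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)


def _geomean_floored(frame: pd.DataFrame) -> pd.Series:
    """Per-lane geometric mean with values floored at 1 (keeps the geomean
    finite in the presence of zero counts; a warning flags floored cells)."""
    vals = frame.to_numpy(dtype=float)
    if (vals < 1).any():
        warnings.warn("control counts < 1 floored at 1 inside the geometric mean")
    gm = np.exp(np.log(np.maximum(vals, 1.0)).mean(axis=0))
    return pd.Series(gm, index=frame.columns)


def _scale_factors(frame: pd.DataFrame, combine: str) -> pd.Series:
    gm = _geomean_floored(frame)
    if (gm <= 0).any():
        lane = gm.index[gm <= 0][0]
        raise ValueError(f"control geometric mean is 0 in lane {lane!r}")
    target = float(gm.mean()) if combine == "arithmetic" else float(np.exp(np.log(gm).mean()))
    return target / gm


def normalize_counts(matrix: CountMatrix,
                     combine: Literal["arithmetic", "geometric"] = "arithmetic",
                     ) -> NormalizationReport:
    """Run the three-step pipeline: background subtraction, positive-spike
    scaling, housekeeping scaling.

    ``combine`` selects how per-lane control geomeans are combined into the
    common target (arithmetic mean across lanes is the vendor-tool
    convention; geometric is exposed as an alternative).  With a single
    lane both factors are exactly 1.
    """
    matrix.require_controls()
    thr = background_threshold(matrix)
    work = matrix.counts.astype(float).copy()
    subtract_rows = matrix.probe_class.isin(["endogenous", "housekeeping"])
    work.loc[subtract_rows] = (work.loc[subtract_rows] - thr).clip(lower=0.0)

    pos_f = _scale_factors(work.loc[matrix.probes_of("positive")], combine)
    work = work * pos_f
    hk_f = _scale_factors(work.loc[matrix.probes_of("housekeeping")], combine)
    work = work * hk_f

    return NormalizationReport(background_threshold=thr, positive_factor=pos_f,
                               housekeeping_factor=hk_f, normalized=work,
                               lane_condition=matrix.lane_condition)


def simulate_counts(base_means: pd.Series, probe_class: pd.Series,
                    lane_condition: pd.Series, lane_scales: pd.Series,
                    fold_changes: Mapping[str, Mapping[str, float]] | None = None,
                    dispersion: float = 0.1, seed: int = 0) -> CountMatrix:
    """Draw a seeded synthetic count matrix with known truth.

    Endogenous, positive and housekeeping probes follow a negative binomial
    with mean ``base_mean x lane_scale`` in the NB1 (linear-overdispersion)
    parametrization, ``var = mu * (1 + dispersion)`` — digital counting is
    close to Poisson, with ``dispersion`` the fractional extra-Poisson
    variance.  Endogenous means are additionally multiplied by the probe's
    fold change in lanes of an affected condition
    (``fold_changes[condition][probe]``).  Negative probes are low-mean
    Poisson background, unaffected by lane scale or condition.
    Deterministic given ``seed``.
    """
    if (base_means <= 0).any():
        raise ValueError("base_means must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if (lane_scales <= 0).any():
        raise ValueError("lane_scales must be > 0")
    fold_changes = fold_changes or {}
    rng = np.random.default_rng(seed)
    probes, lanes = base_means.index, lane_condition.index
    # NB1: var = mu*(1+d)  <=>  NB(size = mu/d, p = 1/(1+d))
    p_nb = 1.0 / (1.0 + dispersion)
    counts = pd.DataFrame(0, index=probes, columns=lanes, dtype=int)
    for lane in lanes:
        cond = lane_condition[lane]
        fc = fold_changes.get(cond, {})
        mu = base_means.copy().astype(float)
        is_neg = probe_class == "negative"
        mu[~is_neg] *= float(lane_scales[lane])
        for probe, f in fc.items():
            if probe_class.get(probe) == "endogenous":
                mu[probe] *= float(f)
        counts.loc[~is_neg, lane] = rng.negative_binomial(mu[~is_neg] / dispersion, p_nb)
        counts.loc[is_neg, lane] = rng.poisson(mu[is_neg])
    return CountMatrix(counts=counts, probe_class=probe_class,
                       lane_condition=lane_condition)


def example_codeset(n_genes: int = 15) -> tuple[pd.Series, pd.Series]:
    """A synthetic probe panel shaped like a small custom CodeSet.

    Returns ``(base_means, probe_class)`` for ``n_genes`` endogenous probes
    with base means log-spaced over 200..2000 counts, 8 negative probes
    (mean 6), a 6-step positive spike-in titration ladder (125..4000) and 3
    housekeeping probes (800..1500).  Purely synthetic — probe names carry
    no biological meaning.
    """
    names, means, classes = [], [], []
    for i, m in enumerate(np.geomspace(200, 2000, n_genes)):
        names.append(f"GENE{i:02d}"); means.append(m); classes.append("endogenous")
    for i in range(8):
        names.append(f"NEG{i}"); means.append(6.0); classes.append("negative")
    for i, m in enumerate(np.geomspace(125, 4000, 6)):
        names.append(f"POS{i}"); means.append(m); classes.append("positive")
    for i, m in enumerate(np.geomspace(800, 1500, 3)):
        names.append(f"HK{i}"); means.append(m); classes.append("housekeeping")
    idx = pd.Index(names, name="probe_id")
    return pd.Series(means, index=idx), pd.Series(classes, index=idx)


def fold_change(report: NormalizationReport, gene: str,
                condition_a: str, condition_b: str,
                n_boot: int = 1000, seed: int = 0) -> dict[str, float]:
    """Ratio of mean normalized counts of ``gene``, condition_b over
    condition_a, with a percentile bootstrap interval over lanes when both
    conditions have >= 3 lanes.

    Returns a dict with ``ratio`` and, when available, ``ci_low``/``ci_high``
    (95% percentile bootstrap).
    """
    lanes_a = report.lane_condition.index[report.lane_condition == condition_a]
    lanes_b = report.lane_condition.index[report.lane_condition == condition_b]
    if len(lanes_a) < 1 or len(lanes_b) < 1:
        raise ValueError("both conditions need at least one lane")
    va = report.normalized.loc[gene, lanes_a].to_numpy(float)
    vb = report.normalized.loc[gene, lanes_b].to_numpy(float)
    ma = float(va.mean())
    if ma == 0:
        raise ValueError(f"zero mean normalized count for {gene!r} in {condition_a!r}")
    out = {"ratio": float(vb.mean()) / ma}
    if len(va) >= 3 and len(vb) >= 3:
        rng = np.random.default_rng(seed)
        ratios = np.empty(n_boot)
        for i in range(n_boot):
            ra = va[rng.integers(0, len(va), len(va))].mean()
            rb = vb[rng.integers(0, len(vb), len(vb))].mean()
            ratios[i] = rb / ra if ra > 0 else np.nan
        lo, hi = np.nanpercentile(ratios, [2.5, 97.5])
        out.update(ci_low=float(lo), ci_high=float(hi))
    return out
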