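"""Inter-sample enrichment scores and significance tests for splice events.

For each splice event ``spl`` and sample ``i`` in a run of ``n`` equally
processed samples:

* pseudocount ``pc_i = max(10, 0.01 * s_i)`` damps noise at low coverage;
* relative read count ``l_i = (r_i + pc_i) / (s_i + pc_i)`` (with
  pseudocounts) and ``l'_i = r_i / s_i`` (without, 0 when ``s_i = 0``);
* enrichment score ``ERS_i = l'_i / mean_{j != i}(l_j)``. The numerator is
  the raw ratio so that absent coverage can never look enriched (with
  pseudocounts alone, ``r = s = 0`` would give ``l = 1``); the denominator
  keeps pseudocounts so the background mean is strictly positive. A neutral
  event shared equally by all samples scores ~1; a sample-specific aberrant
  event scores far above 1 and depresses the reference junctions around it
  below 1.

Significance uses proportion tests on square-root transformed counts
(``sqrt(r_i)`` successes out of ``sqrt(s_i)`` trials). Overlapping reads
make raw counts non-independent; the square root shrinks the effective
trial number to reflect the diminishing marginal information of additional
reads. Two tests are reported per event:

* ``p_all`` — two-tailed chi-square homogeneity across all samples (no
  continuity correction): are the proportions the same in every sample?
* ``p_sample`` — one-tailed pooled two-proportion z-test of sample ``i``
  against the pooled background ``sqrt(sum_{j != i} r_j)`` out of
  ``sqrt(sum_{j != i} s_j)``, small only in the enrichment direction.

Note ``p_all`` may fall below a cutoff while every ``p_sample`` stays above
it: the read distribution differs between samples but no single sample is
enriched — typical for a reference junction depleted in one sample.

The scorer is an sklearn-style transformer over the long-format count
matrix produced by :mod:`splicenrich.discovery`.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: columns appended to the count matrix by :class:`EnrichmentScorer`
RECORD_COLUMNS = ["pc", "l", "l_raw", "ers", "p_all", "p_sample", "n"]

PSEUDOCOUNT_FLOOR = 10.0
PSEUDOCOUNT_RATE = 0.01


def pseudocount(s) -> np.ndarray | float:
    """Pseudocount for a spanning read count: ``max(10, 0.01 * s)``.

    Real-valued, no rounding; scalar in, scalar out.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("spanning read count must be non-negative")
    pc = np.maximum(PSEUDOCOUNT_FLOOR, PSEUDOCOUNT_RATE * s_arr)
    return float(pc) if np.isscalar(s) or s_arr.ndim == 0 else pc


def relative_read_count(r, s, with_pc: bool = True):
    """Fraction of spanning reads congruent with the splice.

    With pseudocounts: ``(r + pc) / (s + pc)`` — equal to 1 in the extreme
    case of absent coverage (r = s = 0). Without: ``r / s``, defined as 0
    when ``s = 0``.
    """
    r_arr = np.asarray(r, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    if np.any(r_arr > s_arr):
        raise ValueError("congruent reads r cannot exceed spanning reads s")
    if np.any(r_arr < 0):
        raise ValueError("read counts must be non-negative")
    if with_pc:
        pc = np.maximum(PSEUDOCOUNT_FLOOR, PSEUDOCOUNT_RATE * s_arr)
        out = (r_arr + pc) / (s_arr + pc)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s_arr > 0, r_arr / np.where(s_arr > 0, s_arr, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def enrichment_score(
    i: int, r: Sequence[float], s: Sequence[float], numerator_pseudocounts: bool = False
) -> float:
    """Enrichment of sample ``i`` relative to the other samples.

    ``ERS_i = l'_i / mean_{j != i}(l_j)`` with the numerator raw by default
    (``numerator_pseudocounts=True`` switches to the fully pseudocounted
    variant for comparison). Requires at least two samples.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    n = len(r)
    if n < 2:
        raise ValueError("enrichment score needs at least 2 samples")
    l_pc = relative_read_count(r, s, with_pc=True)
    num = l_pc[i] if numerator_pseudocounts else relative_read_count(r[i], s[i], with_pc=False)
    background = (l_pc.sum() - l_pc[i]) / (n - 1)
    return float(num / background)


def _sqrt_props(r, s):
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    return np.sqrt(r), np.sqrt(s)


def prop_test_all(r: Sequence[float], s: Sequence[float]) -> float:
    """Two-tailed k-sample homogeneity test on sqrt-transformed counts.

    Chi-square statistic on successes ``sqrt(r_i)`` out of trials
    ``sqrt(s_i)``, without continuity correction; the transformed values are
    used as-is (non-integer). Samples with ``s_i = 0`` are excluded; with
    fewer than two usable samples the p-value is undefined (NaN). A fully
    homogeneous table (all proportions equal, or all successes 0) gives
    statistic 0 and p = 1.
    """
    x, m = _sqrt_props(r, s)
    keep = m > 0
    x, m = x[keep], m[keep]
    k = len(m)
    if k < 2:
        return float("nan")
    p_hat = x.sum() / m.sum()
    if p_hat <= 0.0 or p_hat >= 1.0:
        return 1.0
    chi2 = float(np.sum((x - m * p_hat) ** 2 / (m * p_hat * (1.0 - p_hat))))
    return float(sps.chi2.sf(chi2, df=k - 1))


def prop_test_sample(i: int, r: Sequence[float], s: Sequence[float]) -> float:
    """One-tailed enrichment test of sample ``i`` against the pooled rest.

    Pooled two-proportion z-test on sqrt-transformed counts: sample
    ``sqrt(r_i) / sqrt(s_i)`` versus background ``sqrt(sum_{j != i} r_j) /
    sqrt(sum_{j != i} s_j)`` (square roots of the sums, not sums of square
    roots). Small p-values arise only when the sample's proportion exceeds
    the background; a depleted sample scores p >= 0.5. Undefined (NaN) when
    either side has no spanning reads.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(r) < 2:
        raise ValueError("prop_test_sample needs at least 2 samples")
    s_bg = s.sum() - s[i]
    r_bg = r.sum() - r[i]
    if s_bg <= 0 or s[i] <= 0:
        return float("nan")
    x1, n1 = np.sqrt(r[i]), np.sqrt(s[i])
    x2, n2 = np.sqrt(r_bg), np.sqrt(s_bg)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var <= 0:
        return 0.5  # both proportions at the same boundary: no evidence either way
    z = (p1 - p2) / np.sqrt(var)
    return float(sps.norm.sf(z))


class EnrichmentScorer:
    """Transformer computing enrichment records over a run's count matrix.

    Parameters
    ----------
    numerator_pseudocounts:
        Use the fully pseudocounted relative read count in the ERS numerator
        instead of the raw ratio. Off by default: the raw numerator prevents
        low-coverage samples from looking enriched purely through
        pseudocounts.
    min_group:
        Recommended minimum number of samples per run (warning below it).
    bh_correction:
        Append Benjamini-Hochberg adjusted columns ``q_all``/``q_sample``.
        This is an extension beyond the raw p < cutoff workflow.

    After :meth:`fit`, ``samples_`` and ``n_samples_`` describe the run;
    :meth:`transform` returns the count matrix with :data:`RECORD_COLUMNS`
    appended (one record per sample x event).
    """

    def __init__(
        self,
        numerator_pseudocounts: bool = False,
        min_group: int = 4,
        bh_correction: bool = False,
    ):
        self.numerator_pseudocounts = numerator_pseudocounts
        self.min_group = min_group
        self.bh_correction = bh_correction

    # -- sklearn estimator plumbing ------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "numerator_pseudocounts": self.numerator_pseudocounts,
            "min_group": self.min_group,
            "bh_correction": self.bh_correction,
        }

    def set_params(self, **params) -> "EnrichmentScorer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for EnrichmentScorer")
            setattr(self, key, value)
        return self

    # ------------------------------------------------------------------
    def _validate(self, counts: pd.DataFrame) -> pd.DataFrame:
        required = {"sample_id", "contig", "intron_start", "intron_end", "r", "s"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"count matrix lacks columns {sorted(missing)}")
        if (counts["r"] > counts["s"]).any():
            raise ValueError("count matrix violates r <= s")
        return counts

    def fit(self, counts: pd.DataFrame, y=None) -> "EnrichmentScorer":
        counts = self._validate(counts)
        self.samples_ = list(dict.fromkeys(counts["sample_id"]))
        self.n_samples_ = len(self.samples_)
        if self.n_samples_ < 2:
            raise ValueError(
                "enrichment scoring needs at least 2 samples in the run "
                f"(got {self.n_samples_}); scores are undefined for a single sample"
            )
        if self.n_samples_ < self.min_group:
            warnings.warn(
                f"run has {self.n_samples_} samples; at least {self.min_group} "
                "equally processed samples are recommended",
                stacklevel=2,
            )
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "samples_"):
            raise RuntimeError("EnrichmentScorer is not fitted")
        counts = self._validate(counts).copy().reset_index(drop=True)
        extra = set(counts["sample_id"]) - set(self.samples_)
        if extra:
            raise ValueError(
                f"samples {sorted(extra)} were not part of the fitted run; "
                "enrichment is defined only within one run"
            )
        n = self.n_samples_
        order = {sid: k for k, sid in enumerate(self.samples_)}
        key_cols = ["contig", "intron_start", "intron_end"]

        counts["pc"] = pseudocount(counts["s"].to_numpy())
        counts["l"] = relative_read_count(
            counts["r"].to_numpy(), counts["s"].to_numpy(), with_pc=True
        )
        counts["l_raw"] = relative_read_count(
            counts["r"].to_numpy(), counts["s"].to_numpy(), with_pc=False
        )

        ers = np.empty(len(counts))
        p_all = np.empty(len(counts))
        p_sample = np.empty(len(counts))
        for key, group in counts.groupby(key_cols, sort=False):
            if len(group) != n:
                raise ValueError(
                    f"event {key} has {len(group)} rows for {n} samples; the "
                    "count matrix must be dense (one row per sample x event)"
                )
            idx = group.index.to_numpy()
            rank = np.argsort([order[sid] for sid in group["sample_id"]], kind="stable")
            idx = idx[rank]
            r_vec = counts.loc[idx, "r"].to_numpy(dtype=float)
            s_vec = counts.loc[idx, "s"].to_numpy(dtype=float)
            l_pc = counts.loc[idx, "l"].to_numpy()
            num = l_pc if self.numerator_pseudocounts else counts.loc[idx, "l_raw"].to_numpy()
            background = (l_pc.sum() - l_pc) / (n - 1)
            ers[idx] = num / background
            pa = prop_test_all(r_vec, s_vec)
            p_all[idx] = pa
            p_sample[idx] = [prop_test_sample(i, r_vec, s_vec) for i in range(len(idx))]
        counts["ers"] = ers
        counts["p_all"] = p_all
        counts["p_sample"] = p_sample
        counts["n"] = n
        if self.bh_correction:
            counts["q_all"] = _benjamini_hochberg(counts["p_all"].to_numpy())
            counts["q_sample"] = _benjamini_hochberg(counts["p_sample"].to_numpy())
        return counts

    def fit_transform(self, counts: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(counts).transform(counts)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs propagate."""
    q = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


def compute_run(
    matrix: pd.DataFrame,
    numerator_pseudocounts: bool = False,
    min_group: int = 4,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Score a run's count matrix; thin wrapper over :class:`EnrichmentScorer`."""
    scorer = EnrichmentScorer(
        numerator_pseudocounts=numerator_pseudocounts,
        min_group=min_group,
        bh_correction=bh_correction,
    )
    return scorer.fit_transform(matrix)
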