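"""Statistical selection of the most group-discriminative brain node.

The selection procedure works on spectral power rather than raw amplitudes:

1. estimate the Welch power spectral density of every node's BOLD signal;
2. z-score all PSD values of one subject jointly (over nodes x frequencies),
   removing per-site scale, then average over frequency to get one score per
   node per subject;
3. run a one-way fixed-effects ANOVA across diagnostic groups at every node;
4. keep nodes with p <= alpha, ranked by ascending p (ties broken by node
   index); the first is the top-ranked node used to seed the coherence step.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .dataset import Cohort


class RankingError(ValueError):
    """Raised for inputs on which the ranking procedure is undefined."""


class DegeneratePsdError(RankingError):
    """Raised when a subject's PSD is constant and cannot be z-scored."""


@dataclasses.dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings: 64-sample Hamming segments, 50% overlap."""

    nperseg: int = 64
    overlap: float = 0.5
    window: str = "hamming"
    detrend: str = "constant"

    @property
    def noverlap(self) -> int:
        return int(self.nperseg * self.overlap)


@dataclasses.dataclass
class PsdEstimate:
    """Welch PSD of one subject: ``power[node, frequency]`` on a shared grid."""

    frequencies: np.ndarray  # (n_freqs,), Hz, strictly increasing
    power: np.ndarray  # (n_nodes, n_freqs), >= 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.frequencies) <= 0):
            raise RankingError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise RankingError("PSD power must be non-negative")
        if self.power.shape[1] != self.frequencies.size:
            raise RankingError("power/frequency shape mismatch")


def welch_psd(
    data: np.ndarray,
    tr_seconds: float,
    config: WelchConfig = WelchConfig(),
) -> PsdEstimate:
    """Welch PSD per node of a ``(time,)`` or ``(time x nodes)`` signal array."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n_time = data.shape[0]
    if config.nperseg > n_time:
        raise RankingError(
            f"Welch segment length {config.nperseg} exceeds signal length {n_time}"
        )
    freqs, power = scipy.signal.welch(
        data,
        fs=1.0 / tr_seconds,
        window=config.window,
        nperseg=config.nperseg,
        noverlap=config.noverlap,
        detrend=config.detrend,
        axis=0,
    )
    return PsdEstimate(frequencies=freqs, power=power.T)


def summarize_psd(
    psd: PsdEstimate,
    exclude_dc: bool = True,
    band: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Per-node scores: joint z-score over nodes x frequencies, then average
    over frequency.

    The joint z-score makes scores invariant to any affine per-subject
    distortion of the PSD (site gain/offset) while preserving between-node
    contrasts.  ``band`` optionally restricts the average to a frequency
    window (Hz); by default all bins except DC enter.
    """
    mask = np.ones(psd.frequencies.size, dtype=bool)
    if exclude_dc:
        mask &= psd.frequencies > 0
    if band is not None:
        lo, hi = band
        mask &= (psd.frequencies >= lo) & (psd.frequencies <= hi)
    if not mask.any():
        raise RankingError("no frequency bins left after band selection")
    values = psd.power[:, mask]
    sd = values.std()
    if sd == 0:
        raise DegeneratePsdError("constant PSD: z-scoring undefined for this subject")
    z = (values - values.mean()) / sd
    return z.mean(axis=1)


def anova(group_samples: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: returns ``(F, p)``.

    Degenerate conventions: all observations identical -> (0, 1), an
    uninformative node; zero within-group variance with distinct group means
    -> (inf, 0).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in group_samples]
    if len(groups) < 2:
        raise RankingError("ANOVA needs >= 2 groups")
    for g in groups:
        if g.size < 2:
            raise RankingError("ANOVA needs >= 2 observations per group")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    scale = max(abs(grand), 1.0)
    tiny = np.finfo(float).eps * n_total * scale**2 * 100
    if ssw <= tiny:
        if ssb <= tiny:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = float(scipy.stats.f.sf(f_stat, k - 1, n_total - k))
    return float(f_stat), p


def anova_pvalue(group_samples: Sequence[np.ndarray]) -> float:
    return anova(group_samples)[1]


@dataclasses.dataclass
class NodeRankingResult:
    """Per-node ANOVA p-values and the ranked significant-node list."""

    p_values: np.ndarray  # (n_nodes,), in [0, 1]
    significant_nodes: list[int]  # p <= alpha, ascending p, ties by index
    top_node: Optional[int]  # first significant node, None if none
    alpha: float = 0.05
    node_names: Optional[list[str]] = None

    @property
    def has_top(self) -> bool:
        return self.top_node is not None

    def to_frame(self) -> pd.DataFrame:
        """Ranking report: one row per node with p-value and rank (NA if n.s.)."""
        n = self.p_values.size
        rank = np.full(n, np.nan)
        for r, j in enumerate(self.significant_nodes, start=1):
            rank[j] = r
        frame = pd.DataFrame(
            {
                "node": np.arange(n),
                "p_value": self.p_values,
                "rank": rank,
            }
        )
        if self.node_names is not None:
            frame.insert(1, "node_name", self.node_names)
        return frame


def subject_node_scores(
    cohort: Cohort,
    welch_config: WelchConfig = WelchConfig(),
    band: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, list[str]]:
    """Matrix of per-subject node scores ``(n_subjects x n_nodes)`` + labels."""
    scores = np.empty((len(cohort), cohort.n_nodes))
    labels: list[str] = []
    for i, rec in enumerate(cohort.recordings):
        psd = welch_psd(rec.data, rec.tr_seconds, welch_config)
        scores[i] = summarize_psd(psd, band=band)
        labels.append(rec.group)
    return scores, labels


def rank_nodes(
    cohort: Cohort,
    alpha: float = 0.05,
    welch_config: WelchConfig = WelchConfig(),
    band: Optional[tuple[float, float]] = None,
) -> NodeRankingResult:
    """Rank nodes by ANOVA p-value of mean normalized PSD across groups.

    No multiple-testing correction is applied: the raw per-node p is
    thresholded at ``alpha`` (a Bonferroni-adjusted alpha can be passed
    explicitly by the caller).
    """
    if not cohort.recordings:
        raise RankingError("cannot rank nodes of an empty cohort")
    group_labels = cohort.groups
    if len(group_labels) < 2:
        raise RankingError("node ranking needs >= 2 groups in the cohort")
    scores, labels = subject_node_scores(cohort, welch_config, band)
    labels_arr = np.asarray(labels)

    n_nodes = scores.shape[1]
    p_values = np.empty(n_nodes)
    for j in range(n_nodes):
        samples = [scores[labels_arr == g, j] for g in group_labels]
        p_values[j] = anova_pvalue(samples)

    significant = [int(j) for j in np.lexsort((np.arange(n_nodes), p_values))
                   if p_values[j] <= alpha]
    top = significant[0] if significant else None
    return NodeRankingResult(
        p_values=p_values,
        significant_nodes=significant,
        top_node=top,
        alpha=alpha,
        node_names=cohort.node_names,
    )
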