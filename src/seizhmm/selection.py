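"""Feature ranking (mRMR) and HMM topology selection (AICc).

Two complementary reductions of model complexity:

* **mRMR** ranks wavelet features by the quotient ``V_F / W_c`` of their
  relevance to the chronic-seizure state (one-way ANOVA F-statistic against
  the binary chronic/non-chronic labels) over their redundancy (mean
  absolute Pearson correlation with the other candidate features).  Large
  quotient = informative and non-redundant.

* **AICc** scores every (Q, M) topology on a held-out sequence with the
  small-sample-corrected Akaike information criterion using the parameter
  count ``K = 3QM + Q^2``; after rescaling to the grid minimum, the chosen
  topology is the one with the fewest parameters among those within
  ``delta_aicc < 0.25`` of the best.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .features import FeatureMatrix
from .gmmhmm import FitResult, em_fit, forward_backward

__all__ = [
    "MrmrResult",
    "AiccEntry",
    "AiccGrid",
    "mrmr_rank",
    "aicc",
    "select_topology",
    "grid_search",
]

log = logging.getLogger(__name__)

AICC_THRESHOLD = 0.25  # delta-AICc band for "indistinguishable from best"


@dataclass
class MrmrResult:
    """Feature ranking by the relevance/redundancy quotient, best first."""

    ranking: list[str]
    vf: dict[str, float]
    wc: dict[str, float]
    quotient: dict[str, float]

    def top(self, k: int) -> list[str]:
        return self.ranking[: int(k)]


@dataclass(frozen=True)
class AiccEntry:
    Q: int
    M: int
    K: int
    loglik: float
    aicc: float
    delta_aicc: float = float("nan")


@dataclass
class AiccGrid:
    entries: list[AiccEntry]
    n: int

    def __post_init__(self) -> None:
        if self.entries:
            best = min(e.aicc for e in self.entries)
            self.entries = [
                AiccEntry(e.Q, e.M, e.K, e.loglik, e.aicc, e.aicc - best)
                for e in self.entries
            ]

    def to_dict(self) -> dict:
        return {"n": self.n,
                "entries": [vars(e) for e in self.entries]}


def mrmr_rank(f: FeatureMatrix, target: np.ndarray) -> MrmrResult:
    """Rank features by V_F / W_c against a binary chronic-state target.

    V_F is the one-way ANOVA F-statistic of the feature grouped by the
    target; W_c the mean absolute Pearson correlation with the other
    candidates (defined as 1 for a single candidate).  Zero-variance
    features get quotient 0 and are ranked last.
    """
    target = np.asarray(target).astype(bool).ravel()
    if target.size != f.T:
        raise ValueError("target length must match window count")
    if f.T < 10:
        raise ValueError("need at least 10 windows for a meaningful ranking")
    if target.all() or not target.any():
        raise ValueError("target must contain both classes")

    X = f.x
    D = f.D
    stds = X.std(axis=0, ddof=0)
    degenerate = stds == 0.0
    if degenerate.any():
        warnings.warn("zero-variance feature(s) ranked last", stacklevel=2)

    # pairwise |Pearson| among non-degenerate candidates
    corr = np.zeros((D, D))
    ok = ~degenerate
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok].T)
        corr[np.ix_(ok, ok)] = np.abs(sub)

    vf, wc, quotient = {}, {}, {}
    for d, name in enumerate(f.band_labels):
        if degenerate[d]:
            vf[name], wc[name], quotient[name] = 0.0, 1.0, 0.0
            continue
        F = stats.f_oneway(X[target, d], X[~target, d]).statistic
        vf[name] = float(F) if np.isfinite(F) else 0.0
        others = [j for j in range(D) if j != d and not degenerate[j]]
        wc[name] = float(np.mean(corr[d, others])) if others else 1.0
        quotient[name] = vf[name] / wc[name] if wc[name] > 0 else 0.0

    order = sorted(range(D), key=lambda d: -quotient[f.band_labels[d]])
    ranking = [f.band_labels[d] for d in order]
    return MrmrResult(ranking=ranking, vf=vf, wc=wc, quotient=quotient)


def aicc(loglik: float, Q: int, M: int, n: int) -> float:
    """Corrected Akaike information criterion for a (Q, M) topology.

    ``K = 3QM + Q^2``; AICc = -2 LL + 2K + 2K(K+1)/(n - K - 1).  The
    correction term is always applied (it vanishes as n grows) and requires
    ``n > K + 1``.
    """
    K = 3 * Q * M + Q * Q
    if n <= K + 1:
        raise ValueError(f"n={n} too small for K={K} parameters (need n > K+1)")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def select_topology(grid: AiccGrid, threshold: float = AICC_THRESHOLD) -> tuple[int, int]:
    """Smallest model statistically tied with the best: minimum K among
    entries with ``delta_aicc < threshold`` (ties -> smaller Q, then M)."""
    if not grid.entries:
        raise ValueError("empty AICc grid")
    qualifying = [e for e in grid.entries if e.delta_aicc < threshold]
    best = min(qualifying, key=lambda e: (e.K, e.Q, e.M))
    return best.Q, best.M


def grid_search(f: Union[FeatureMatrix, Sequence[FeatureMatrix]],
                eval_f: Optional[Union[FeatureMatrix, Sequence[FeatureMatrix]]] = None,
                Q_range: Sequence[int] = range(1, 11),
                M_range: Sequence[int] = range(1, 6),
                seed: int = 0, n_restarts: int = 3,
                **fit_kwargs) -> tuple[AiccGrid, dict[tuple[int, int], FitResult]]:
    """Fit every (Q, M) topology and score it by AICc on held-out data.

    ``f`` is the training sequence(s); ``eval_f`` the evaluation sequence
    whose window count is the ``n`` of the AICc correction (defaults to the
    training data itself).  Cells whose fit fails, or whose K is too large
    for the evaluation size, are excluded with a warning.  Returns the
    rescaled grid plus the per-cell fit results.
    """
    if eval_f is None:
        eval_f = f
    eval_seqs = [eval_f] if isinstance(eval_f, (FeatureMatrix, np.ndarray)) else list(eval_f)
    n_eval = sum(s.x.shape[0] if isinstance(s, FeatureMatrix) else s.shape[0]
                 for s in eval_seqs)

    entries: list[AiccEntry] = []
    fits: dict[tuple[int, int], FitResult] = {}
    for Q in Q_range:
        for M in M_range:
            K = 3 * Q * M + Q * Q
            if n_eval <= K + 1:
                log.warning("skipping (Q=%d, M=%d): n=%d too small for K=%d", Q, M, n_eval, K)
                continue
            cell_seed = int(np.random.SeedSequence((seed, Q, M)).generate_state(1)[0] % (2 ** 31))
            try:
                fit = em_fit(f, Q, M, seed=cell_seed, n_restarts=n_restarts, **fit_kwargs)
                ll_eval = sum(forward_backward(fit.model, s).loglik for s in eval_seqs)
            except (FloatingPointError, ValueError) as exc:
                log.warning("cell (Q=%d, M=%d) failed: %s", Q, M, exc)
                continue
            fits[(Q, M)] = fit
            entries.append(AiccEntry(Q, M, K, float(ll_eval), aicc(ll_eval, Q, M, n_eval)))
    return AiccGrid(entries=entries, n=n_eval), fits
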