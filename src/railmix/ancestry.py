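"""Two-cluster admixture estimation and site purity rules.

Two estimators are provided. ``supervised_q`` fixes the cluster allele
frequencies at known parental values and solves a bounded one-dimensional
maximum-likelihood problem per individual. ``unsupervised_em`` jointly
estimates per-individual cluster memberships and per-cluster allele
frequencies by EM on the allele-copy mixture model (maximum-likelihood
analogue of model-based clustering with admixture), restarted from
``n_starts`` random initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DataError, ParameterError
from .panel import PanelSpec

KING = "KING"
CLAPPER = "CLAPPER"
ADMIXED = "ADMIXED"
PURE_KING = "PURE_KING"
PURE_CLAPPER = "PURE_CLAPPER"

_EPS = 1e-300


@dataclass
class AdmixtureResult:
    """Cluster memberships, cluster allele frequencies and model fit.

    ``q`` has one row per individual and one column per cluster (rows sum to
    1); ``freqs`` has one row per cluster giving the allele-1 frequency at
    each locus. Individuals with zero scored loci get NaN memberships and
    are listed in ``flagged``.
    """

    q: pd.DataFrame
    freqs: pd.DataFrame
    log_likelihood: float
    K: int
    converged: bool
    n_iterations: int
    flagged: list[str] = field(default_factory=list)
    loglik_history: np.ndarray | None = None
    start_logliks: list[float] = field(default_factory=list)

    @property
    def q_king(self) -> pd.Series:
        if KING not in self.q.columns:
            raise DataError("result has no KING-anchored cluster; anchor labels first")
        return self.q[KING]


def _loglik_q(q: float, g: np.ndarray, p_k: np.ndarray, p_c: np.ndarray) -> float:
    """Allele-copy mixture log-likelihood for one individual at fixed freqs."""
    p1 = q * p_k + (1 - q) * p_c  # P(king-associated allele copy)
    ll_1 = np.where(p1 > 0, np.log(np.maximum(p1, _EPS)), -np.inf)
    ll_0 = np.where(p1 < 1, np.log(np.maximum(1 - p1, _EPS)), -np.inf)
    # guard 0 * -inf at boundary q
    with np.errstate(invalid="ignore"):
        t1 = np.where(g > 0, g * ll_1, 0.0)
        t0 = np.where(g < 2, (2 - g) * ll_0, 0.0)
        return float(np.sum(t1) + np.sum(t0))


def _maximize_q(g: np.ndarray, p_k: np.ndarray, p_c: np.ndarray) -> float:
    """Bounded scalar ML estimate of the mixture proportion q on [0, 1]."""
    res = optimize.minimize_scalar(
        lambda q: -_loglik_q(q, g, p_k, p_c),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # boundary MLEs: the bounded method stops short of the endpoints
    candidates = [float(res.x), 0.0, 1.0]
    values = [_loglik_q(q, g, p_k, p_c) for q in candidates]
    return candidates[int(np.argmax(values))]


def supervised_q(genotypes: pd.DataFrame, panel: PanelSpec) -> AdmixtureResult:
    """Per-individual king-cluster membership with parental frequencies fixed.

    Maximizes the allele-copy mixture likelihood over q in [0, 1] for each
    individual independently. Individuals with no scored loci get NaN and
    are flagged.
    """
    cols = [c for c in genotypes.columns if c in set(panel.locus_ids)]
    if not cols:
        raise DataError("no panel loci present in genotype matrix")
    sub = panel.subset(cols)
    g_all = genotypes[cols].to_numpy(dtype=float)
    p_k, p_c = sub.p_king, sub.p_clapper

    q_king = np.full(len(genotypes), np.nan)
    total_ll = 0.0
    flagged = []
    for i, sid in enumerate(genotypes.index):
        mask = ~np.isnan(g_all[i])
        if not mask.any():
            flagged.append(sid)
            continue
        g = g_all[i, mask]
        q_hat = _maximize_q(g, p_k[mask], p_c[mask])
        q_king[i] = q_hat
        total_ll += _loglik_q(q_hat, g, p_k[mask], p_c[mask])
    q = pd.DataFrame(
        {KING: q_king, CLAPPER: 1 - q_king}, index=genotypes.index.copy()
    )
    freqs = pd.DataFrame(
        [p_k, p_c], index=[KING, CLAPPER], columns=cols
    )
    return AdmixtureResult(
        q=q,
        freqs=freqs,
        log_likelihood=total_ll,
        K=2,
        converged=True,
        n_iterations=0,
        flagged=flagged,
    )


def _em_loglik(g: np.ndarray, obs: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    p1 = q @ f  # (n, L) marginal allele-1 probability per individual-locus
    p0 = q @ (1 - f)
    ll1 = np.where(p1 > 0, np.log(np.maximum(p1, _EPS)), -np.inf)
    ll0 = np.where(p0 > 0, np.log(np.maximum(p0, _EPS)), -np.inf)
    a = np.where(obs, np.nan_to_num(g), 0.0)
    b = np.where(obs, 2 - np.nan_to_num(g), 0.0)
    # guard 0 * -inf where a count is zero against a boundary frequency
    with np.errstate(invalid="ignore"):
        t1 = np.where(a > 0, a * ll1, 0.0)
        t0 = np.where(b > 0, b * ll0, 0.0)
        return float(t1.sum() + t0.sum())


def _em_single_start(
    g: np.ndarray,
    obs: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    track_history: bool,
) -> tuple[np.ndarray, np.ndarray, float, bool, int, np.ndarray | None]:
    n, L = g.shape
    a = np.nan_to_num(g) * obs  # allele-1 copies
    b = (2 - np.nan_to_num(g)) * obs  # allele-2 copies
    copies = (a + b).sum(axis=1)  # 2 * scored loci per individual

    q = rng.dirichlet(np.ones(K), size=n)
    f = rng.uniform(0.05, 0.95, size=(K, L))
    ll = _em_loglik(g, obs, q, f)
    history = [ll] if track_history else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities per allele copy
        num1 = q[:, :, None] * f[None, :, :]  # (n, K, L)
        num0 = q[:, :, None] * (1 - f)[None, :, :]
        r1 = num1 / np.maximum(num1.sum(axis=1, keepdims=True), _EPS)
        r0 = num0 / np.maximum(num0.sum(axis=1, keepdims=True), _EPS)
        w1 = a[:, None, :] * r1  # expected allele-1 copies from cluster k
        w0 = b[:, None, :] * r0
        # M-step
        q = (w1 + w0).sum(axis=2) / np.maximum(copies, 1)[:, None]
        # renormalize to kill accumulation error; all-missing rows stay uniform
        q = q / np.maximum(q.sum(axis=1, keepdims=True), _EPS)
        denom = (w1 + w0).sum(axis=0)
        f = np.where(denom > 0, w1.sum(axis=0) / np.maximum(denom, _EPS), f)
        f = np.clip(f, 0.0, 1.0)
        new_ll = _em_loglik(g, obs, q, f)
        if track_history:
            history.append(new_ll)
        if new_ll - ll < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return q, f, ll, converged, it, (np.asarray(history) if track_history else None)


def unsupervised_em(
    genotypes: pd.DataFrame,
    K: int = 2,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_starts: int = 5,
    seed: int = 0,
    anchor_panel: PanelSpec | None = None,
    track_history: bool = False,
) -> AdmixtureResult:
    """Maximum-likelihood admixture by block-ascent EM, best of ``n_starts``.

    Cluster allele frequencies are independent across clusters and loci.
    When ``anchor_panel`` is given, cluster labels are anchored by matching
    the estimated frequency vectors to the panel's parental frequencies
    (resolving EM label switching); otherwise clusters are named
    ``cluster1..K``.
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")
    g = genotypes.to_numpy(dtype=float)
    obs = ~np.isnan(g)
    scored_per_ind = obs.sum(axis=1)
    flagged = genotypes.index[scored_per_ind == 0].tolist()

    rng = np.random.default_rng(seed)
    best = None
    start_logliks: list[float] = []
    for _ in range(n_starts):
        result = _em_single_start(g, obs, K, rng, tol, max_iter, track_history)
        start_logliks.append(result[2])
        if best is None or result[2] > best[2]:
            best = result
    q, f, ll, converged, n_iter, history = best

    labels = [f"cluster{k + 1}" for k in range(K)]
    q_df = pd.DataFrame(q, index=genotypes.index.copy(), columns=labels)
    q_df.loc[flagged] = np.nan
    f_df = pd.DataFrame(f, index=labels, columns=genotypes.columns.copy())
    result = AdmixtureResult(
        q=q_df,
        freqs=f_df,
        log_likelihood=ll,
        K=K,
        converged=converged,
        n_iterations=n_iter,
        flagged=flagged,
        loglik_history=history,
        start_logliks=start_logliks,
    )
    if anchor_panel is not None and K == 2:
        result = anchor_labels(result, anchor_panel)
    return result


def anchor_labels(result: AdmixtureResult, panel: PanelSpec) -> AdmixtureResult:
    """Rename EM clusters by matching frequencies to the panel's parental values.

    Chooses the cluster-to-species assignment minimizing total squared
    distance between estimated and reference allele-frequency vectors.
    Only defined for K=2 (KING vs CLAPPER).
    """
    if result.K != 2:
        raise ParameterError("label anchoring is defined for K=2")
    cols = [c for c in result.freqs.columns if c in set(panel.locus_ids)]
    sub = panel.subset(cols)
    ref = np.vstack([sub.p_king, sub.p_clapper])  # rows: KING, CLAPPER
    est = result.freqs[cols].to_numpy(dtype=float)
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(2)):
        cost = float(((est[list(perm)] - ref) ** 2).sum())
        if cost < best_cost:
            best_perm, best_cost = list(perm), cost
    labels_old = list(result.freqs.index)
    order = [labels_old[i] for i in best_perm]
    q = result.q[order].copy()
    q.columns = [KING, CLAPPER]
    freqs = result.freqs.loc[order].copy()
    freqs.index = [KING, CLAPPER]
    return AdmixtureResult(
        q=q,
        freqs=freqs,
        log_likelihood=result.log_likelihood,
        K=result.K,
        converged=result.converged,
        n_iterations=result.n_iterations,
        flagged=result.flagged,
        loglik_history=result.loglik_history,
        start_logliks=result.start_logliks,
    )


@dataclass(frozen=True)
class SitePurity:
    site_id: str
    status: str  # PURE_KING | PURE_CLAPPER | ADMIXED
    min_q_max: float


def classify_sites(
    q_by_site: Mapping[str, Sequence[float]],
    q_pure: float = 0.98,
) -> list[SitePurity]:
    """Classify sampling sites as pure (one species) or admixed.

    ``q_by_site`` maps site ids to the per-individual king-cluster
    memberships (q_king in [0, 1]). A site is PURE_KING (PURE_CLAPPER) iff
    every individual has max-species Q >= ``q_pure`` toward king (clapper);
    any individual below the cutoff — or a site split between species —
    makes the site ADMIXED.
    """
    out = []
    for site_id, qs in q_by_site.items():
        qs = np.asarray(list(qs), dtype=float)
        if qs.size == 0:
            raise DataError(f"site {site_id!r} has no individuals")
        q_max = np.maximum(qs, 1 - qs)
        min_q_max = float(q_max.min())
        if min_q_max >= q_pure:
            all_king = bool(np.all(qs >= 0.5))
            all_clapper = bool(np.all(qs < 0.5))
            if all_king:
                status = PURE_KING
            elif all_clapper:
                status = PURE_CLAPPER
            else:
                status = ADMIXED  # all-pure but split between species
        else:
            status = ADMIXED
        out.append(SitePurity(site_id, status, min_q_max))
    return out
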