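"""Event-based model of biomarker abnormality ordering.

Disease progression is treated as a fixed sequence S of N "events", each
the transition of one biomarker from a normal to an abnormal level.
Cross-sectional measurements x_j of subject j are explained by an
unknown stage k: biomarkers placed at positions <= k in S have gone
abnormal, the rest are still normal. With per-biomarker event
distributions p(x | E) (abnormal) and p(x | not E) (normal), the
sequence likelihood marginalizes the stage uniformly:

    P(X | S) = prod_j (1/(N+1)) * sum_{k=0}^{N}
               prod_{i<=k} p(x_{S(i),j} | E) * prod_{i>k} p(x_{S(i),j} | not E)

The normal component of each event distribution is pinned to the
non-carrier sample; the abnormal component and mixing weight are fitted
to carriers with the normal component frozen. Missing measurements enter
both products with one equal constant, so they cancel from every
likelihood ratio and cannot influence the inferred ordering.

Sequence inference: greedy ascent over single-event repositions from
random restarts (maximum likelihood), Metropolis-Hastings over
permutations for posterior uncertainty, and a subject-level bootstrap
for cross-validated positional variance. Staging assigns each
subject-visit the stage maximizing its likelihood under the ML sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .preprocess import AdjustedPanel

__all__ = [
    "EventDistribution",
    "EventModel",
    "SubjectLikelihoods",
    "SequencePosterior",
    "StageAssignment",
    "fit_event_distributions",
    "compute_likelihoods",
    "sequence_log_likelihood",
    "find_ml_sequence",
    "mcmc_sample_sequences",
    "bootstrap_sequence",
    "stage_subjects",
]

log = logging.getLogger(__name__)

#: Densities are floored at this value before taking logs.
DENSITY_FLOOR = 1e-250
#: Equal likelihood assigned to a missing cell under both hypotheses.
MISSING_LIKELIHOOD = 0.5


@dataclass(frozen=True)
class EventDistribution:
    """Normal and abnormal Gaussian components for one biomarker, plus the
    mixing weight of the *normal* component among carriers."""

    name: str
    mu_normal: float
    sd_normal: float
    mu_abnormal: float
    sd_abnormal: float
    weight_normal: float
    direction: int

    def p_normal(self, x):
        return stats.norm.pdf(x, self.mu_normal, self.sd_normal)

    def p_abnormal(self, x):
        return stats.norm.pdf(x, self.mu_abnormal, self.sd_abnormal)


@dataclass
class EventModel:
    """Per-biomarker event distributions (the EBM measurement model)."""

    events: dict  # name -> EventDistribution

    @property
    def biomarkers(self):
        return list(self.events)

    @classmethod
    def from_specs(cls, specs, weight_normal: float = 0.5) -> "EventModel":
        """Build directly from generative biomarker specs (used for
        noise-free checks where fitting is degenerate)."""
        events = {
            s.name: EventDistribution(
                name=s.name, mu_normal=s.normal_mean, sd_normal=s.normal_sd,
                mu_abnormal=s.abnormal_mean, sd_abnormal=s.abnormal_sd,
                weight_normal=weight_normal, direction=s.direction)
            for s in specs
        }
        return cls(events=events)


@dataclass
class SubjectLikelihoods:
    """log p(x | E) and log p(x | not E) per subject-visit and biomarker."""

    log_p_event: np.ndarray     # (n_rows, n_events)
    log_p_normal: np.ndarray    # (n_rows, n_events)
    missing: np.ndarray         # (n_rows, n_events) bool
    biomarkers: list
    index: pd.DataFrame         # subject_id, visit_index per row

    @property
    def n_events(self) -> int:
        return len(self.biomarkers)


@dataclass
class SequencePosterior:
    """ML ordering plus MCMC (or bootstrap) samples over orderings."""

    ml_sequence: list                      # biomarker names in event order
    ml_log_likelihood: float
    samples: np.ndarray | None = None      # (n_samples, N) int positions
    sample_log_likelihoods: np.ndarray | None = None
    positional_variance: np.ndarray | None = None  # (N, N)
    acceptance_rate: float | None = None
    biomarkers: list = field(default_factory=list)

    def positional_variance_frame(self) -> pd.DataFrame:
        pv = self.positional_variance
        return pd.DataFrame(pv, index=self.biomarkers,
                            columns=[f"pos_{k}" for k in range(pv.shape[1])])


@dataclass
class StageAssignment:
    """Most probable stage per subject-visit under a fixed sequence."""

    stages: pd.DataFrame        # subject_id, visit_index, stage, all_missing
    posteriors: np.ndarray      # (n_rows, N+1)


# ---------------------------------------------------------------------------
# Event distributions

def _fit_one_mixture(values: np.ndarray, mu_n: float, sd_n: float,
                     direction: int, min_separation: float = 1.0) -> tuple:
    """Maximize the carrier mixture likelihood over (weight_normal,
    mu_abnormal, sd_abnormal) with the normal component frozen.

    Constraints: mu_abnormal on the pathological side of mu_normal, at
    least ``min_separation`` normal-sds away (without a separation floor
    the fit is degenerate when few carriers are abnormal: an
    "abnormal" component hugging the normal one with weight ~1 has the
    same likelihood as the intended solution but destroys staging);
    sd_abnormal >= 0.1 * sd_normal. Three deterministic starts.
    """
    x = values[np.isfinite(values)]
    span = max(np.ptp(x), sd_n)
    lo_sd = 0.1 * sd_n
    hi_sd = max(5.0 * np.std(x), 2 * sd_n)
    if direction > 0:
        mu_bounds = (mu_n + min_separation * sd_n, mu_n + 10 * span)
    else:
        mu_bounds = (mu_n - 10 * span, mu_n - min_separation * sd_n)

    def nll(theta):
        w, mu_a, sd_a = theta
        p = (w * stats.norm.pdf(x, mu_n, sd_n)
             + (1 - w) * stats.norm.pdf(x, mu_a, sd_a))
        return -np.sum(np.log(np.maximum(p, DENSITY_FLOOR)))

    qlo, qhi = np.percentile(x, [10, 90])
    far = qhi if direction > 0 else qlo
    far = min(max(far, mu_bounds[0]), mu_bounds[1])
    mid = min(max(mu_n + direction * 2 * sd_n, mu_bounds[0]), mu_bounds[1])
    starts = [
        (0.5, far, max(np.std(x) / 2, lo_sd)),
        (0.7, mid, max(sd_n, lo_sd)),
        (0.3, far, max(sd_n, lo_sd)),
    ]
    bounds = [(0.01, 0.99), mu_bounds, (lo_sd, hi_sd)]
    best = None
    for s0 in starts:
        res = optimize.minimize(nll, s0, method="L-BFGS-B", bounds=bounds)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("mixture optimization failed from all starts")
    w, mu_a, sd_a = best.x
    return float(w), float(mu_a), float(sd_a)


def fit_event_distributions(panel: AdjustedPanel, biomarkers: list,
                            directions: dict | None = None,
                            table: pd.DataFrame | None = None,
                            min_separation: float = 1.0,
                            anchor_to_symptomatic: bool = True) -> EventModel:
    """Fit the two-component measurement model per biomarker on baseline
    rows: normal component = non-carrier mean/sd (kept fixed), abnormal
    component and mixing weight fitted to all carriers, with the abnormal
    mean constrained to the pathological side at least ``min_separation``
    normal-sds from the normal mean.

    With ``anchor_to_symptomatic`` (default) the separation floor is
    additionally raised to half a normal-sd below the symptomatic-carrier
    median when at least five symptomatic values exist: the abnormal
    level is by definition the level seen in symptomatic patients, and
    without this anchor the weight/mean trade-off of the heavily
    overlapping mixture lets the abnormal mean collapse toward the
    normal component on gradually-transitioning biomarkers."""
    if directions is None:
        directions = panel.directions or {}
    bl = table if table is not None else panel.baseline()
    controls = bl[~bl["carrier"].astype(bool)]
    carriers = bl[bl["carrier"].astype(bool)]
    events = {}
    for b in biomarkers:
        cv = controls[b].dropna().to_numpy(float)
        xv = carriers[b].dropna().to_numpy(float)
        if len(cv) < 3 or len(xv) < 3:
            raise ValueError(f"too few observed values for biomarker {b!r}")
        mu_n, sd_n = float(np.mean(cv)), float(np.std(cv, ddof=1))
        sym = carriers[carriers["cdr_global"] > 0][b].dropna()
        d = directions.get(b)
        if d is None:
            ref = sym.median() if len(sym) else np.median(xv)
            d = int(np.sign(ref - mu_n)) or 1
        sep = min_separation
        if anchor_to_symptomatic and len(sym) >= 5:
            z_sym = d * (float(sym.median()) - mu_n) / sd_n
            sep = max(sep, z_sym - 0.5)
        w, mu_a, sd_a = _fit_one_mixture(xv, mu_n, sd_n, d,
                                         min_separation=sep)
        events[b] = EventDistribution(name=b, mu_normal=mu_n, sd_normal=sd_n,
                                      mu_abnormal=mu_a, sd_abnormal=sd_a,
                                      weight_normal=w, direction=d)
    return EventModel(events=events)


def compute_likelihoods(data, model: EventModel,
                        biomarkers: list | None = None) -> SubjectLikelihoods:
    """Evaluate per-cell event/normal likelihoods for each row of ``data``
    (a DataFrame or an AdjustedPanel; typically carrier rows)."""
    if isinstance(data, AdjustedPanel):
        data = data.table
    biomarkers = list(biomarkers if biomarkers is not None else model.biomarkers)
    n = len(data)
    N = len(biomarkers)
    lE = np.empty((n, N))
    lN = np.empty((n, N))
    miss = np.zeros((n, N), dtype=bool)
    logc = np.log(MISSING_LIKELIHOOD)
    for j, b in enumerate(biomarkers):
        ev = model.events[b]
        x = data[b].to_numpy(float)
        m = ~np.isfinite(x)
        pe = ev.p_abnormal(np.where(m, 0.0, x))
        pn = ev.p_normal(np.where(m, 0.0, x))
        lE[:, j] = np.where(m, logc, np.log(np.maximum(pe, DENSITY_FLOOR)))
        lN[:, j] = np.where(m, logc, np.log(np.maximum(pn, DENSITY_FLOOR)))
        miss[:, j] = m
    idx = data[["subject_id", "visit_index"]].reset_index(drop=True)
    return SubjectLikelihoods(log_p_event=lE, log_p_normal=lN, missing=miss,
                              biomarkers=biomarkers, index=idx)


# ---------------------------------------------------------------------------
# Sequence likelihood

def _stage_terms(L: SubjectLikelihoods, order: np.ndarray) -> np.ndarray:
    """log prod-terms per subject and stage k = 0..N for one ordering."""
    d = L.log_p_event[:, order] - L.log_p_normal[:, order]
    base = L.log_p_normal.sum(axis=1, keepdims=True)
    prefix = np.concatenate([np.zeros((d.shape[0], 1)), np.cumsum(d, axis=1)], axis=1)
    return base + prefix  # (n, N+1)


def sequence_log_likelihood(order, L: SubjectLikelihoods) -> float:
    """Stage-marginalized log-likelihood of one ordering (uniform prior on
    the N+1 stages), computed in log space with a log-sum-exp guard."""
    order = np.asarray(order, dtype=int)
    N = L.n_events
    if sorted(order.tolist()) != list(range(N)):
        raise ValueError("order must be a permutation of the event indices")
    terms = _stage_terms(L, order)
    return float(np.sum(logsumexp(terms, axis=1) - np.log(N + 1)))


def _batch_log_likelihood(orders: np.ndarray, L: SubjectLikelihoods) -> np.ndarray:
    """Vectorized sequence log-likelihood for a batch of orderings (B, N)."""
    d = L.log_p_event - L.log_p_normal          # (n, N)
    base = L.log_p_normal.sum()                 # scalar: sum over all cells
    # (n, B, N): per-subject deltas arranged along each candidate ordering
    dp = d[:, orders]
    prefix = np.cumsum(dp, axis=2)
    n, B, N = prefix.shape
    terms = np.concatenate([np.zeros((n, B, 1)), prefix], axis=2)
    ll = logsumexp(terms, axis=2) - np.log(N + 1)   # (n, B)
    return base + ll.sum(axis=0)


# ---------------------------------------------------------------------------
# ML sequence by greedy ascent

def _reposition_candidates(order: np.ndarray) -> np.ndarray:
    """All orderings reachable by moving one event to another position."""
    N = len(order)
    cands = []
    for i in range(N):
        rest = np.delete(order, i)
        for j in range(N):
            if j == i:
                continue
            cands.append(np.insert(rest, j, order[i]))
    return np.array(cands)


def find_ml_sequence(L: SubjectLikelihoods, n_restarts: int = 10,
                     rng=None) -> tuple:
    """Greedy ascent over single-event repositions from random restart
    permutations; returns (best order, best log-likelihood). The first
    restart starts from the identity ordering, so likelihood ties between
    identical biomarker columns resolve to input order."""
    rng = np.random.default_rng(rng)
    N = L.n_events
    if N == 1:
        return np.array([0]), sequence_log_likelihood([0], L)
    best_order, best_ll = None, -np.inf
    for r in range(max(1, n_restarts)):
        order = np.arange(N) if r == 0 else rng.permutation(N)
        ll = _batch_log_likelihood(order[None, :], L)[0]
        while True:
            cands = _reposition_candidates(order)
            lls = _batch_log_likelihood(cands, L)
            k = int(np.argmax(lls))
            if lls[k] > ll + 1e-12:
                order, ll = cands[k], lls[k]
            else:
                break
        if ll > best_ll:
            best_order, best_ll = order, float(ll)
    return best_order, best_ll


# ---------------------------------------------------------------------------
# MCMC over orderings

def positional_variance_from_samples(samples: np.ndarray) -> np.ndarray:
    """pv[i, k] = fraction of sampled orderings placing event i at
    position k. Every row and column sums to one."""
    n_samples, N = samples.shape
    pv = np.zeros((N, N))
    for s in samples:
        pv[s, np.arange(N)] += 1.0
    return pv / n_samples


def mcmc_sample_sequences(L: SubjectLikelihoods, init,
                          n_samples: int = 100_000, burn_in: int = 10_000,
                          thin: int = 10, rng=None) -> SequencePosterior:
    """Metropolis-Hastings over permutations with a uniform sequence
    prior. Proposal: swap two positions chosen uniformly (symmetric), so
    acceptance reduces to the likelihood ratio. Retains every ``thin``-th
    post-burn-in sample and summarizes them as a positional variance
    matrix."""
    rng = np.random.default_rng(rng)
    order = np.asarray(init, dtype=int).copy()
    N = L.n_events
    ll = sequence_log_likelihood(order, L)
    best_order, best_ll = order.copy(), ll
    kept = []
    kept_ll = []
    n_accept = 0
    total = burn_in + n_samples
    for it in range(total):
        i, j = rng.integers(0, N, size=2)
        if i == j:
            prop_ll = ll
            accepted = True
            prop = order
        else:
            prop = order.copy()
            prop[i], prop[j] = prop[j], prop[i]
            prop_ll = sequence_log_likelihood(prop, L)
            accepted = np.log(rng.random()) < (prop_ll - ll)
        if accepted:
            order, ll = prop, prop_ll
            n_accept += 1
            if ll > best_ll:
                best_order, best_ll = order.copy(), ll
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept.append(order.copy())
            kept_ll.append(ll)
    rate = n_accept / total
    if not (0.02 <= rate <= 0.9):
        log.warning("MCMC acceptance rate %.3f outside [0.02, 0.9]", rate)
    samples = np.array(kept)
    pv = positional_variance_from_samples(samples)
    names = [L.biomarkers[i] for i in best_order]
    return SequencePosterior(ml_sequence=names, ml_log_likelihood=best_ll,
                             samples=samples,
                             sample_log_likelihoods=np.array(kept_ll),
                             positional_variance=pv, acceptance_rate=rate,
                             biomarkers=list(L.biomarkers))


# ---------------------------------------------------------------------------
# Bootstrap cross-validation

def bootstrap_sequence(panel: AdjustedPanel, biomarkers: list,
                       n_boot: int = 100, n_restarts: int = 10,
                       directions: dict | None = None,
                       rng=None) -> SequencePosterior:
    """Refit event distributions and the ML sequence on subject-level
    bootstrap resamples (carriers and non-carriers resampled within
    group); the positional variance is the fraction of bootstrap ML
    sequences placing each event at each position."""
    rng = np.random.default_rng(rng)
    bl = panel.baseline().reset_index(drop=True)
    carriers = bl[bl["carrier"].astype(bool)].reset_index(drop=True)
    controls = bl[~bl["carrier"].astype(bool)].reset_index(drop=True)
    orders = []
    lls = []
    for _ in range(n_boot):
        for attempt in range(100):
            rc = carriers.iloc[rng.integers(0, len(carriers), len(carriers))]
            rn = controls.iloc[rng.integers(0, len(controls), len(controls))]
            if len(rc) >= 3 and len(rn) >= 3:
                break
            log.warning("bootstrap resample with tiny group; redrawing")
        resample = pd.concat([rn, rc], ignore_index=True)
        model = fit_event_distributions(panel, biomarkers,
                                        directions=directions, table=resample)
        Lb = compute_likelihoods(resample[resample["carrier"].astype(bool)],
                                 model, biomarkers)
        order, ll = find_ml_sequence(Lb, n_restarts=n_restarts, rng=rng)
        orders.append(order)
        lls.append(ll)
    samples = np.array(orders)
    pv = positional_variance_from_samples(samples)
    k = int(np.argmax(lls))
    names = [biomarkers[i] for i in samples[k]]
    return SequencePosterior(ml_sequence=names, ml_log_likelihood=float(lls[k]),
                             samples=samples, sample_log_likelihoods=np.array(lls),
                             positional_variance=pv, biomarkers=list(biomarkers))


# ---------------------------------------------------------------------------
# Staging

def stage_subjects(L: SubjectLikelihoods, order) -> StageAssignment:
    """Stage posterior over k = 0..N per subject-visit under the fixed
    ordering; assignment is the argmax with ties broken toward the
    earlier stage. All-missing rows receive a uniform posterior and are
    flagged."""
    order = np.asarray(order, dtype=int)
    terms = _stage_terms(L, order)                 # (n, N+1)
    post = np.exp(terms - logsumexp(terms, axis=1, keepdims=True))
    all_missing = L.missing.all(axis=1)
    post[all_missing] = 1.0 / post.shape[1]
    stages = np.argmax(post, axis=1)               # argmax -> first (earlier) tie
    out = L.index.copy()
    out["stage"] = stages
    out["all_missing"] = all_missing
    return StageAssignment(stages=out, posteriors=post)
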