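"""Mk-model inference and stochastic character mapping on dated trees,
and dispersal-through-time counting.

The character is the operational unit a species occupies (k states, one per
unit). Evolution along the tree follows a continuous-time Markov chain with
generator Q, either equal-rates (ER: one rate for every transition) or
all-rates-different (ARD: k(k-1) free rates). The root state prior is
uniform (1/k).

Stochastic mapping samples complete character histories conditional on the
tip states and Q: node states are drawn from their joint conditional
distribution (root from its posterior, then pre-order conditional sampling),
and each branch path is drawn conditional on its endpoint states by
rejection sampling of CTMC paths, falling back to uniformization sampling
after 1,000 rejected attempts on a branch.

A dispersal is a sampled transition between two units; dispersals are
binned by transition age (bins lower-inclusive from the present: a
transition at age a falls in bin floor(a / bin_width)), and "relative"
counts divide by the number of lineages alive at each bin midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize as sopt
from scipy import stats as sps

from .tree import Node, Tree

RATE_MIN = 1e-9
RATE_MAX = 1e3
#: rejection attempts per branch before switching to uniformization sampling
MAX_REJECTIONS = 1000


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model


@dataclass
class MkModel:
    """A k-state CTMC generator over named states (operational units)."""

    states: tuple[str, ...]
    Q: np.ndarray
    structure: str = "ER"
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise PhyloError(f"Q must be {k}x{k} for {k} states")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise PhyloError("off-diagonal rates must be >= 0")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-12 * max(1.0, np.abs(self.Q).max())):
            raise PhyloError("Q rows must sum to 0")

    @property
    def k(self) -> int:
        return len(self.states)

    @classmethod
    def er(cls, states, rate: float) -> "MkModel":
        """Equal-rates model: every off-diagonal entry equals ``rate``."""
        k = len(states)
        Q = np.full((k, k), rate, dtype=float)
        np.fill_diagonal(Q, -(k - 1) * rate)
        return cls(tuple(states), Q, "ER")


def transition_matrices(Q: np.ndarray, lengths) -> np.ndarray:
    """P(t) = expm(Q t) for each branch length, via eigendecomposition with a
    dense-expm fallback for ill-conditioned generators."""
    ts = np.atleast_1d(np.asarray(lengths, dtype=float))
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        E = np.exp(np.multiply.outer(ts, w))  # (n, k)
        P = np.einsum("ij,nj,jl->nil", V, E, Vinv).real
    else:
        P = np.stack([sla.expm(Q * t) for t in ts])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# likelihood (Felsenstein pruning)


def _tip_partial(state: str, sidx: dict[str, int], k: int) -> np.ndarray:
    L = np.zeros(k)
    try:
        L[sidx[state]] = 1.0
    except KeyError:
        raise PhyloError(f"tip state {state!r} not in model state set") from None
    return L


def _pruning(tree: Tree, tip_states: dict[str, str], model: MkModel):
    """Post-order conditional likelihoods, rescaled per node.

    Returns (partials, log_scale, P) where partials[node] is the rescaled
    conditional likelihood of the subtree below the node given each state,
    and P[node] the transition matrix on the branch above the node.
    """
    k = model.k
    sidx = {s: i for i, s in enumerate(model.states)}
    nodes = tree.postorder()
    nonroot = [n for n in nodes if n.parent is not None]
    Ps = transition_matrices(model.Q, [n.length for n in nonroot])
    P = {n: Ps[i] for i, n in enumerate(nonroot)}
    partials: dict[Node, np.ndarray] = {}
    log_scale = 0.0
    for node in nodes:
        if node.is_tip:
            name = node.name or ""
            if name not in tip_states:
                raise PhyloError(f"no state supplied for tip {name!r}")
            L = _tip_partial(tip_states[name], sidx, k)
        else:
            L = np.ones(k)
            for c in node.children:
                L = L * (P[c] @ partials[c])
            m = L.max()
            if m <= 0.0:
                return partials, -np.inf, P
            L = L / m
            log_scale += np.log(m)
        partials[node] = L
    return partials, log_scale, P


def mk_likelihood(tree: Tree, tip_states: dict[str, str], model: MkModel) -> float:
    """Log-likelihood of the tip states under Q, uniform root prior 1/k."""
    partials, log_scale, _ = _pruning(tree, tip_states, model)
    if np.isneginf(log_scale):
        return -np.inf
    root_sum = partials[tree.root].sum() / model.k
    if root_sum <= 0.0:
        return -np.inf
    return float(np.log(root_sum) + log_scale)


# ---------------------------------------------------------------------------
# fitting


def fit_mk(
    tree: Tree,
    tip_states: dict[str, str],
    structure: str = "ER",
    states: tuple[str, ...] | None = None,
) -> MkModel:
    """Maximum-likelihood Mk fit by bounded derivative-free optimisation.

    Rates are bounded in [1e-9, 1e3] events/Myr and optimised on the log
    scale. With all tips in one state the rate is not identifiable: the
    lower-bound model is returned with a warning.
    """
    if states is None:
        states = tuple(sorted(set(tip_states.values())))
    k = len(states)
    if k < 2:
        raise PhyloError("need at least 2 states in the state set")
    observed = {tip_states[t] for t in tree.tip_names()}
    if len(observed) < 2:
        warnings.warn(
            "all tips share one state; transition rate is unidentifiable, "
            "returning the lower-bound rate", stacklevel=2
        )
        model = MkModel.er(states, RATE_MIN)
        model.log_likelihood = mk_likelihood(tree, tip_states, model)
        return model

    lo, hi = np.log(RATE_MIN), np.log(RATE_MAX)

    if structure == "ER":
        def nll(log_q: float) -> float:
            return -mk_likelihood(tree, tip_states, MkModel.er(states, np.exp(log_q)))

        res = sopt.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        model = MkModel.er(states, float(np.exp(res.x)))
        model.log_likelihood = -float(res.fun)
        return model

    if structure != "ARD":
        raise PhyloError(f"unknown model structure {structure!r} (ER or ARD)")

    offdiag = [(i, j) for i in range(k) for j in range(k) if i != j]

    def build_q(log_rates: np.ndarray) -> np.ndarray:
        Q = np.zeros((k, k))
        for (i, j), lr in zip(offdiag, log_rates):
            Q[i, j] = np.exp(lr)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def nll_vec(log_rates: np.ndarray) -> float:
        return -mk_likelihood(tree, tip_states, MkModel(states, build_q(log_rates), "ARD"))

    er = fit_mk(tree, tip_states, "ER", states)
    x0 = np.full(len(offdiag), np.log(max(er.Q[0, 1] if k > 1 else RATE_MIN, RATE_MIN)))
    res = sopt.minimize(
        nll_vec, x0, method="L-BFGS-B",
        bounds=[(lo, hi)] * len(offdiag), options={"ftol": 1e-10},
    )
    model = MkModel(states, build_q(res.x), "ARD")
    model.log_likelihood = -float(res.fun)
    if er.log_likelihood is not None and model.log_likelihood < er.log_likelihood:
        # ER is nested in ARD; never report a worse ARD optimum
        model = MkModel(states, er.Q.copy(), "ARD")
        model.log_likelihood = er.log_likelihood
    return model


# ---------------------------------------------------------------------------
# stochastic mapping


@dataclass
class CharacterHistory:
    """One sampled state history: node states plus per-branch transition lists.

    ``branch_events[child]`` holds the transitions on the branch above
    ``child`` as (age, from_state, to_state), ordered from older to younger;
    transition ages lie strictly inside the branch's age interval.
    """

    tree: Tree
    states: tuple[str, ...]
    node_states: dict[Node, str]
    branch_events: dict[Node, list[tuple[float, str, str]]]

    @property
    def n_transitions(self) -> int:
        return sum(len(ev) for ev in self.branch_events.values())

    def transitions(self):
        for events in self.branch_events.values():
            yield from events


#: expected uniformized jumps on a branch above which path sampling goes
#: straight to uniformization (rejection attempts would mostly be wasted work)
UNIFORMIZATION_CUTOFF = 5.0


def _simulate_forward_branch(Q: np.ndarray, a: int, t: float, rng) -> tuple[list, int]:
    """Unconditioned CTMC path from state a over duration t.

    Returns (events, end_state) with events as (time_from_start, from, to).
    """
    return _PathSampler(np.asarray(Q, dtype=float)).forward(a, t, rng)


class _PathSampler:
    """CTMC path machinery for one generator Q: fast forward simulation and
    endpoint-conditioned uniformization sampling with cached R powers."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.k = Q.shape[0]
        self.rates = -Q.diagonal()
        # cumulative jump-chain probabilities per current state
        cum = []
        for i in range(self.k):
            p = Q[i].copy()
            p[i] = 0.0
            tot = p.sum()
            cum.append(np.cumsum(p / tot) if tot > 0 else np.zeros(self.k))
        self.cum_jump = cum
        self.mu = float(max(self.rates.max(), 0.0))
        self.R = np.eye(self.k) + (Q / self.mu if self.mu > 0 else 0.0)
        self._Rp = [np.eye(self.k)]

    def _powers(self, n: int):
        while len(self._Rp) <= n:
            self._Rp.append(self._Rp[-1] @ self.R)
        return self._Rp

    def forward(self, a: int, t: float, rng) -> tuple[list, int]:
        events = []
        cur = a
        s = 0.0
        while True:
            rate = self.rates[cur]
            if rate <= 0.0:
                break
            s += rng.exponential(1.0 / rate)
            if s >= t:
                break
            nxt = int(np.searchsorted(self.cum_jump[cur], rng.random()))
            events.append((s, cur, nxt))
            cur = nxt
        return events, cur

    def uniformization(self, a: int, b: int, t: float, rng) -> list:
        """Exact endpoint-conditioned path sample, no rejection."""
        if self.mu <= 0.0:
            return []
        lam = self.mu * t
        N = max(2, int(sps.poisson.ppf(1.0 - 1e-12, lam)) + 2)
        Rp = self._powers(N)
        pmf = sps.poisson.pmf(np.arange(N + 1), lam)
        w = pmf * np.array([Rp[n][a, b] for n in range(N + 1)])
        total = w.sum()
        if total <= 0.0:
            raise PhyloError("endpoint pair has zero probability under Q")
        n = int(np.searchsorted(np.cumsum(w / total), rng.random()))
        # sample the uniformized jump chain bridged to end state b
        chain = [a]
        cur = a
        for step in range(1, n + 1):
            probs = self.R[cur, :] * Rp[n - step][:, b]
            probs = np.cumsum(probs / probs.sum())
            cur = int(np.searchsorted(probs, rng.random()))
            chain.append(cur)
        times = np.sort(rng.random(n)) * t
        return [
            (float(times[i]), chain[i], chain[i + 1])
            for i in range(n)
            if chain[i] != chain[i + 1]
        ]

    def path(self, a: int, b: int, t: float, rng, stats: dict) -> list:
        if self.mu * t > UNIFORMIZATION_CUTOFF:
            stats["n_uniformization_direct"] = stats.get("n_uniformization_direct", 0) + 1
            return self.uniformization(a, b, t, rng)
        for _ in range(MAX_REJECTIONS):
            events, end = self.forward(a, t, rng)
            if end == b:
                return events
        stats["n_uniformization_fallbacks"] = (
            stats.get("n_uniformization_fallbacks", 0) + 1
        )
        return self.uniformization(a, b, t, rng)


def stochastic_map(
    tree: Tree,
    tip_states: dict[str, str],
    model: MkModel,
    n_maps: int,
    rng: np.random.Generator,
    stats: dict | None = None,
) -> list[CharacterHistory]:
    """Sample complete character histories conditional on tips and Q."""
    if stats is None:
        stats = {}
    partials, log_scale, P = _pruning(tree, tip_states, model)
    if np.isneginf(log_scale) or partials[tree.root].sum() <= 0:
        raise PhyloError("tip data have zero likelihood under the model")
    k = model.k
    histories: list[CharacterHistory] = []
    pre = tree.preorder()
    sampler = _PathSampler(model.Q)
    for _ in range(n_maps):
        node_state: dict[Node, int] = {}
        root_p = partials[tree.root] / partials[tree.root].sum()
        node_state[tree.root] = int(rng.choice(k, p=root_p))
        for node in pre:
            if node is tree.root:
                continue
            i = node_state[node.parent]
            probs = P[node][i, :] * partials[node]
            probs = probs / probs.sum()
            node_state[node] = int(rng.choice(k, p=probs))
        branch_events: dict[Node, list[tuple[float, str, str]]] = {}
        for node in pre:
            if node is tree.root:
                continue
            a = node_state[node.parent]
            b = node_state[node]
            path = sampler.path(a, b, node.length, rng, stats)
            start_age = node.age + node.length
            branch_events[node] = [
                (start_age - s, model.states[f], model.states[to])
                for s, f, to in path
            ]
        histories.append(
            CharacterHistory(
                tree,
                model.states,
                {n: model.states[s] for n, s in node_state.items()},
                branch_events,
            )
        )
    return histories


def expected_transitions(Q: np.ndarray, a: int, b: int, t: float) -> float:
    """Exact E[number of state changes | X(0)=a, X(t)=b] by a truncated
    uniformization series (analytic route, independent of the sampler)."""
    mu = float(-np.asarray(Q).diagonal().min())
    if mu <= 0.0:
        return 0.0
    k = Q.shape[0]
    R = np.eye(k) + Q / mu
    M = R.copy()
    np.fill_diagonal(M, 0.0)  # real (state-changing) jumps only
    lam = mu * t
    N = max(2, int(sps.poisson.ppf(1.0 - 1e-12, lam)) + 2)
    pmf = sps.poisson.pmf(np.arange(N + 1), lam)
    Rp = np.eye(k)
    S = np.zeros((k, k))  # S_n = sum_{j=1..n} R^{j-1} M R^{n-j}
    denom = pmf[0] * Rp[a, b]
    num = 0.0
    for n in range(1, N + 1):
        S = R @ S + M @ Rp  # recursion: S_n = R S_{n-1} + M R^{n-1}
        Rp = Rp @ R
        denom += pmf[n] * Rp[a, b]
        num += pmf[n] * S[a, b]
    if denom <= 0.0:
        raise PhyloError("endpoint pair has zero probability under Q")
    return float(num / denom)


# ---------------------------------------------------------------------------
# tip-state reduction


def tip_states_from_coding(
    counts: pd.DataFrame, tip_names: list[str] | None = None
) -> tuple[dict[str, str], dict]:
    """Reduce the count matrix to one unit state per species (majority rule).

    The state is the unit with the species' maximum count; ties break to the
    lexicographically smallest unit name. All-zero species are dropped with
    a warning. If ``tip_names`` is given, species and tips that cannot be
    matched are reported in the log and dropped.
    """
    states: dict[str, str] = {}
    ties: list[str] = []
    zero: list[str] = []
    for sp, row in counts.iterrows():
        mx = row.max()
        if mx <= 0:
            zero.append(sp)
            continue
        best = sorted(c for c in counts.columns if row[c] == mx)
        if len(best) > 1:
            ties.append(sp)
        states[sp] = best[0]
    if zero:
        warnings.warn(
            f"{len(zero)} species with zero occurrences in every unit were "
            "dropped from the character mapping", stacklevel=2
        )
    log = {
        "n_species_coded": len(states),
        "zero_occurrence_species": zero,
        "tied_species": ties,
    }
    if tip_names is not None:
        tips = set(tip_names)
        matched = {s: u for s, u in states.items() if s in tips}
        log["unmatched_tips"] = sorted(tips - set(states))
        log["unmatched_species"] = sorted(set(states) - tips)
        log["n_matched"] = len(matched)
        states = matched
    return states, log


# ---------------------------------------------------------------------------
# dispersal counting


@dataclass
class DispersalSeries:
    """Binned dispersal counts per ordered unit pair, across sampled histories.

    ``values`` has shape (n_samples, n_pairs, n_bins); for the absolute
    series these are integer transition counts, for the relative series they
    are counts divided by contemporaneous lineage numbers (NaN where no
    lineage spans the bin midpoint).
    """

    pair_labels: list[tuple[str, str]]
    bin_edges: np.ndarray  # length n_bins + 1, starting at 0
    values: np.ndarray  # (n_samples, n_pairs, n_bins)
    lineages: np.ndarray | None = None  # (n_samples, n_bins)
    kind: str = "absolute"

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def _frame(self, arr: np.ndarray) -> pd.DataFrame:
        cols = [
            f"[{self.bin_edges[i]:g},{self.bin_edges[i + 1]:g})"
            for i in range(self.n_bins)
        ]
        idx = pd.Index([f"{a}->{b}" for a, b in self.pair_labels], name="pair")
        return pd.DataFrame(arr, index=idx, columns=cols)

    def mean(self) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            return self._frame(np.nanmean(self.values, axis=0))

    def sd(self) -> pd.DataFrame:
        ddof = 1 if self.values.shape[0] > 1 else 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            return self._frame(np.nanstd(self.values, axis=0, ddof=ddof))

    def total(self) -> float:
        return float(np.nansum(self.values))


def history_transition_counts(
    history: CharacterHistory,
    pair_labels: list[tuple[str, str]],
    bin_edges: np.ndarray,
    bin_width: float,
) -> np.ndarray:
    """Exact binned transition counts of one history (pair x bin)."""
    pidx = {p: i for i, p in enumerate(pair_labels)}
    out = np.zeros((len(pair_labels), len(bin_edges) - 1), dtype=np.int64)
    for age, frm, to in history.transitions():
        b = int(np.floor(age / bin_width))
        out[pidx[(frm, to)], b] += 1
    return out


def lineages_through_time(tree: Tree, bin_edges: np.ndarray) -> np.ndarray:
    """Number of branches alive at each bin midpoint.

    A branch spans the age interval (child age, parent age], closed at the
    older end and open at the younger; the root itself has no branch. Bins
    older than the root therefore hold 0 lineages.
    """
    edges = np.asarray(bin_edges, dtype=float)
    mids = (edges[:-1] + edges[1:]) / 2.0
    counts = np.zeros(len(mids), dtype=np.int64)
    for node in tree.preorder():
        if node.parent is None:
            continue
        young, old = node.age, node.age + node.length
        counts += (mids > young) & (mids <= old)
    return counts


def count_dispersals(
    histories: list[CharacterHistory], bin_width: float = 10.0
) -> DispersalSeries:
    """Absolute dispersals per ordered unit pair per time bin.

    A transition at age a falls in bin floor(a / bin_width) (bins
    lower-inclusive from the present). Values are kept per sampled history
    so that means and across-sample standard deviations can be reported;
    lineage counts at bin midpoints are attached for the relative series.
    """
    if not histories:
        raise PhyloError("no histories supplied")
    states = histories[0].states
    pair_labels = [(a, b) for a in states for b in states if a != b]
    max_age = max(h.tree.root_age for h in histories)
    n_bins = max(1, int(np.ceil(max_age / bin_width - 1e-12)))
    bin_edges = np.arange(n_bins + 1, dtype=float) * bin_width
    values = np.zeros((len(histories), len(pair_labels), n_bins))
    lineages = np.zeros((len(histories), n_bins), dtype=np.int64)
    ltt_cache: dict[int, np.ndarray] = {}
    for i, h in enumerate(histories):
        values[i] = history_transition_counts(h, pair_labels, bin_edges, bin_width)
        key = id(h.tree)
        if key not in ltt_cache:
            ltt_cache[key] = lineages_through_time(h.tree, bin_edges)
        lineages[i] = ltt_cache[key]
    return DispersalSeries(pair_labels, bin_edges, values, lineages, "absolute")


def relative_dispersals(series: DispersalSeries) -> DispersalSeries:
    """Lineage-corrected dispersals: absolute counts divided by the number of
    lineages at the bin midpoint; NaN (undefined) where no lineage exists."""
    if series.lineages is None:
        raise PhyloError("series has no lineage counts attached")
    lin = series.lineages[:, None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(lin > 0, series.values / np.where(lin > 0, lin, 1.0), np.nan)
    return DispersalSeries(
        series.pair_labels, series.bin_edges, rel, series.lineages, "relative"
    )


def write_dispersal_tables(
    absolute: DispersalSeries, relative: DispersalSeries, path_prefix
) -> None:
    """Write mean and sd tables (pair x bin) for both series as TSV."""
    prefix = str(path_prefix)
    for series, tag in ((absolute, "absolute"), (relative, "relative")):
        series.mean().to_csv(f"{prefix}_{tag}_mean.tsv", sep="\t")
        series.sd().to_csv(f"{prefix}_{tag}_sd.tsv", sep="\t")


def plot_dispersal_series(series: DispersalSeries, path) -> None:
    """Optional thin line-plot of mean dispersals per pair through time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = series.mean()
    mids = (series.bin_edges[:-1] + series.bin_edges[1:]) / 2.0
    fig, ax = plt.subplots(figsize=(7, 4))
    for pair in mean.index:
        ax.plot(mids, mean.loc[pair], marker="o", label=pair)
    ax.set_xlabel("age (Myr, bin midpoint)")
    ax.set_ylabel(f"{series.kind} dispersals per bin")
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
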