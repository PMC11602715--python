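"""Tree-constrained blocked Gibbs sampler for true VAFs from deep targeted
sequencing, and the clone-fraction statistics derived from its posterior.

Deep targeted counts give a noisy binomial estimate of each mutation's variant
allele fraction (VAF) in a bulk cell fraction, but mutations are not
independent: they sit on a phylogeny, and a descendant branch cannot carry a
higher VAF than its ancestor, while sibling branches' VAFs cannot sum above
their parent's.  The sampler augments the data with per-branch bounds
[kappa_j, lambda_j] and alternates:

* Block 1 — per mutation, a Metropolis-Hastings update of rho_i within its
  branch bounds, using a truncated Beta(rho*sigma/(1-rho), sigma) proposal, a
  Bin(N_i, pi_i) likelihood with pi_i = rho_i + eps_i - 2*rho_i*eps_i, and the
  full Hastings correction for the asymmetric proposal;
* Block 2 — per node (root-to-tip), the "unallocated VAF" between the inbound
  branch's minimum mutation VAF and the outbound branches' maximum VAFs is
  split by uniform order statistics and allocated to the inbound kappa and
  outbound lambdas; the final gap stays unallocated.

The root branch's lambda is fixed at 0.5 (a clonal heterozygous mutation) and
terminal branches' kappa at 1e-10.  Sex-chromosome depths are doubled in
males.  Defaults: 20,000 iterations, 10,000 burn-in, thinning 100 (100
retained draws), sigma = 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .readcounts import TargetedCounts
from .treecore import Node, Phylogeny

__all__ = [
    "BranchBounds",
    "VafChain",
    "estimate_error_rates",
    "expected_variant_fraction",
    "gibbs_run",
    "representative_rank",
    "clone_fractions",
    "sdi",
    "driver_fold_change",
]

TERMINAL_KAPPA = 1e-10
ROOT_LAMBDA = 0.5
_RHO_FLOOR = 1e-9


def estimate_error_rates(control_counts: pd.DataFrame) -> dict[str, float]:
    """Per-mutation sequencing error from control individuals.

    Controls lack the mutations, so their variant reads are pure error.
    ``eps_i = (sum variant + 0.5) / (sum depth + 1)`` pooled across controls
    (a pseudo-count estimator that never returns exactly 0).  Mutations with
    zero control depth get the global median with a warning.
    """
    if control_counts is None or len(control_counts) == 0:
        raise ValueError("no control counts supplied")
    agg = control_counts.groupby("mutation_id")[["variant", "depth"]].sum()
    eps = (agg["variant"] + 0.5) / (agg["depth"] + 1.0)
    zero = agg["depth"] == 0
    if zero.any():
        fallback = float(eps[~zero].median()) if (~zero).any() else 1e-4
        warnings.warn(f"{int(zero.sum())} mutation(s) with zero control depth; "
                      "using global median error rate")
        eps[zero] = fallback
    return eps.to_dict()


def expected_variant_fraction(rho, eps):
    """pi = rho + eps - 2*rho*eps: a variant read is a correctly read mutant
    molecule or an error on a wild-type molecule."""
    rho = np.asarray(rho, dtype=float)
    eps = np.asarray(eps, dtype=float)
    return rho + eps - 2.0 * rho * eps


@dataclass
class BranchBounds:
    """Per-branch VAF bounds, aligned with ``branch_names``."""

    branch_names: list[str]
    kappa: np.ndarray
    lam: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"branch": self.branch_names,
                             "kappa": self.kappa, "lambda": self.lam})


@dataclass
class VafChain:
    """Retained posterior draws of rho per mutation, plus bound chains."""

    mutation_ids: list[str]
    draws: np.ndarray              # (n_retained, n_mutations)
    branch_names: list[str]
    kappa_draws: np.ndarray        # (n_retained, n_branches)
    lambda_draws: np.ndarray
    branch_of: dict[str, str]
    meta: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]

    def median(self) -> pd.Series:
        return pd.Series(np.median(self.draws, axis=0), index=self.mutation_ids)

    def summary(self) -> pd.DataFrame:
        lo, med, hi = np.percentile(self.draws, [2.5, 50, 97.5], axis=0)
        return pd.DataFrame(
            {"median": med, "lo": lo, "hi": hi,
             "branch": [self.branch_of[m] for m in self.mutation_ids]},
            index=self.mutation_ids,
        )


class _GibbsLayout:
    """Static tree layout: branch arrays, per-branch mutations, node structure."""

    def __init__(self, tree: Phylogeny, mut_ids: list[str], branch_of: dict[str, str]):
        self.branch_nodes = tree.branches()  # preorder, root-to-tip
        self.branch_names = [b.name for b in self.branch_nodes]
        index = {n: i for i, n in enumerate(self.branch_names)}
        known = set(self.branch_names)
        for m in mut_ids:
            if branch_of.get(m) not in known:
                raise ValueError(f"mutation {m!r} maps to no branch of the tree")
        self.mut_branch = np.array([index[branch_of[m]] for m in mut_ids])
        self.muts_on = [np.flatnonzero(self.mut_branch == i)
                        for i in range(len(self.branch_names))]
        self.is_terminal = np.array([b.is_leaf for b in self.branch_nodes])
        self.root_unary = len(tree.root.children) == 1
        # which branches have covered mutations in their subtree (self incl.)
        has_mut = {b: self.muts_on[i].size > 0
                   for i, b in enumerate(self.branch_names)}
        below: dict[str, bool] = {}
        for node in tree.postorder():
            flag = has_mut.get(node.name, False)
            for c in node.children:
                flag = flag or below[c.name]
            below[node.name] = flag
        self.has_mut_below = below
        # Block-2 nodes: a node only partitions VAF if some outbound subtree
        # carries covered mutations; otherwise there is nothing to allocate
        # and its branches' bounds are left alone.  The zygote acts as a
        # virtual inbound with fixed VAF 0.5 when the root multifurcates; a
        # unary root instead pins its single branch's lambda at 0.5.
        self.nodes = []
        for node in tree.preorder():
            if node.is_leaf:
                continue
            if not any(below[c.name] for c in node.children):
                continue
            if node.parent is None and self.root_unary:
                continue
            inbound = index[node.name] if node.parent is not None else -1
            outbound = [index[c.name] for c in node.children]
            self.nodes.append((inbound, outbound))


def _loglik(rho, eps, Y, N):
    pi = np.clip(expected_variant_fraction(rho, eps), 1e-300, 1 - 1e-15)
    return Y * np.log(pi) + (N - Y) * np.log1p(-pi)


def gibbs_run(
    tree: Phylogeny,
    counts: TargetedCounts,
    sample: str | None = None,
    iterations: int = 20_000,
    burn_in: int = 10_000,
    thin: int = 100,
    sigma: float = 50.0,
    male: bool = False,
    seed: int | None = None,
) -> VafChain:
    """Run the blocked Gibbs sampler for one bulk sample.

    Returns a :class:`VafChain` with ``(iterations - burn_in) / thin`` retained
    draws per mutation and the matching kappa/lambda bound chains.  Every
    retained draw satisfies its branch bounds and the nesting constraint
    (sum of outbound lambdas <= inbound kappa) to machine precision.
    """
    if sample is None:
        samples = counts.samples
        if len(samples) != 1:
            raise ValueError("counts hold several samples; pass sample=...")
        sample = samples[0]
    tab = counts.for_sample(sample)
    mut_ids = list(tab.index)
    if not mut_ids:
        raise ValueError(f"no counts for sample {sample!r}")
    layout = _GibbsLayout(tree, mut_ids, counts.branch_of)
    Y = tab["variant"].to_numpy(dtype=float)
    N = tab["depth"].to_numpy(dtype=float)
    if male:
        xy = np.array([bool(counts.is_xy.get(m, False)) for m in mut_ids])
        N = np.where(xy, 2.0 * N, N)
    eps = np.array([float(counts.error_rates.get(m, 0.0)) for m in mut_ids])
    if (eps < 0).any() or (eps >= 0.5).any():
        raise ValueError("error rates must lie in [0, 0.5)")

    rng = np.random.default_rng(seed)
    n_mut = len(mut_ids)
    n_branch = len(layout.branch_names)

    # --- initialisation: raw VAFs, then a feasibility pass -----------------
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(N > 0, Y / np.maximum(N, 1.0), 0.0)
    rho = np.clip(rho, _RHO_FLOOR, ROOT_LAMBDA - 1e-6)
    rho = _repair_feasibility(rho, layout)
    kappa, lam = _initial_bounds(rho, layout)

    n_retained = (iterations - burn_in) // thin
    draws = np.empty((n_retained, n_mut))
    kap_draws = np.empty((n_retained, n_branch))
    lam_draws = np.empty((n_retained, n_branch))
    r = 0
    for k in range(1, iterations + 1):
        _block1_update(rho, kappa, lam, layout.mut_branch, eps, Y, N, sigma, rng)
        _block2_update(rho, kappa, lam, layout, rng)
        if k > burn_in and (k - burn_in) % thin == 0:
            draws[r] = rho
            kap_draws[r] = kappa
            lam_draws[r] = lam
            r += 1
    meta = {"iterations": iterations, "burn_in": burn_in, "thin": thin,
            "sigma": sigma, "seed": seed, "sample": sample, "male": male}
    return VafChain(mut_ids, draws, layout.branch_names, kap_draws, lam_draws,
                    {m: layout.branch_names[b] for m, b in zip(mut_ids, layout.mut_branch)},
                    meta)


def _repair_feasibility(rho: np.ndarray, layout: _GibbsLayout) -> np.ndarray:
    """Scale subtree VAFs down until every node satisfies the nesting rule."""
    rho = rho.copy()
    # iterate bottom-up needs until stable (trees are shallow; few passes)
    for _ in range(100):
        need = _branch_needs(rho, layout)
        changed = False
        for inbound, outbound in layout.nodes:
            cap = ROOT_LAMBDA if inbound < 0 else (
                rho[layout.muts_on[inbound]].min()
                if layout.muts_on[inbound].size else ROOT_LAMBDA
            )
            total = sum(need[c] for c in outbound)
            if total > cap:
                f = (cap / total) * (1.0 - 1e-9)
                for c in outbound:
                    _scale_subtree(rho, layout, c, f)
                changed = True
        if not changed:
            break
    return rho


def _branch_needs(rho: np.ndarray, layout: _GibbsLayout) -> np.ndarray:
    """Bottom-up: the VAF headroom each branch requires from its parent."""
    need = np.full(len(layout.branch_names), TERMINAL_KAPPA)
    children: dict[int, list[int]] = {}
    for inbound, outbound in layout.nodes:
        if inbound >= 0:
            children[inbound] = outbound
    for i in reversed(range(len(layout.branch_names))):  # preorder reversed
        own = rho[layout.muts_on[i]].max() if layout.muts_on[i].size else 0.0
        below = sum(need[c] for c in children.get(i, []))
        need[i] = max(own, below, TERMINAL_KAPPA)
    return need


def _scale_subtree(rho: np.ndarray, layout: _GibbsLayout, branch: int, f: float):
    stack = [branch]
    children: dict[int, list[int]] = {}
    for inbound, outbound in layout.nodes:
        if inbound >= 0:
            children[inbound] = outbound
    while stack:
        b = stack.pop()
        idx = layout.muts_on[b]
        if idx.size:
            rho[idx] = np.maximum(rho[idx] * f, _RHO_FLOOR)
        stack.extend(children.get(b, []))


def _initial_bounds(rho: np.ndarray, layout: _GibbsLayout
                    ) -> tuple[np.ndarray, np.ndarray]:
    need = _branch_needs(rho, layout)
    children: dict[int, list[int]] = {}
    for inbound, outbound in layout.nodes:
        if inbound >= 0:
            children[inbound] = outbound
    lam = need.copy()
    kappa = np.empty_like(lam)
    for i in range(len(lam)):
        below = sum(need[c] for c in children.get(i, []))
        kappa[i] = below if children.get(i) else TERMINAL_KAPPA
    if layout.root_unary:
        lam[0] = ROOT_LAMBDA  # preorder: branch 0 is the root branch
    kappa = np.minimum(kappa, lam)
    kappa[layout.is_terminal] = TERMINAL_KAPPA
    return kappa, lam


def _block1_update(rho, kappa, lam, mut_branch, eps, Y, N, sigma, rng) -> None:
    """Vectorised Metropolis-Hastings update of every mutation's VAF."""
    k_i = kappa[mut_branch]
    l_i = lam[mut_branch]
    rho[:] = np.clip(rho, k_i, l_i)
    width = l_i - k_i
    live = width > 1e-13
    a = np.maximum(rho, _RHO_FLOOR) * sigma / (1.0 - np.maximum(rho, _RHO_FLOOR))
    a = np.maximum(a, 1e-12)
    Flo = special.betainc(a, sigma, np.clip(k_i, 0, 1))
    Fhi = special.betainc(a, sigma, np.clip(l_i, 0, 1))
    span = Fhi - Flo
    live &= span > 1e-300
    u = Flo + rng.random(rho.size) * span
    with np.errstate(all="ignore"):
        prop = special.betaincinv(a, sigma, np.clip(u, 0, 1))
    prop = np.clip(prop, k_i, l_i)
    # forward proposal density (truncated beta)
    with np.errstate(all="ignore"):
        log_q_fwd = (
            (a - 1.0) * np.log(np.maximum(prop, 1e-300))
            + (sigma - 1.0) * np.log1p(-np.minimum(prop, 1 - 1e-15))
            - special.betaln(a, sigma) - np.log(np.maximum(span, 1e-300))
        )
        a2 = np.maximum(prop, _RHO_FLOOR) * sigma / (1.0 - np.maximum(prop, _RHO_FLOOR))
        a2 = np.maximum(a2, 1e-12)
        Flo2 = special.betainc(a2, sigma, np.clip(k_i, 0, 1))
        Fhi2 = special.betainc(a2, sigma, np.clip(l_i, 0, 1))
        span2 = np.maximum(Fhi2 - Flo2, 1e-300)
        log_q_rev = (
            (a2 - 1.0) * np.log(np.maximum(rho, 1e-300))
            + (sigma - 1.0) * np.log1p(-np.minimum(rho, 1 - 1e-15))
            - special.betaln(a2, sigma) - np.log(span2)
        )
        log_alpha = (
            _loglik(prop, eps, Y, N) - _loglik(rho, eps, Y, N)
            + log_q_rev - log_q_fwd
        )
    accept = live & np.isfinite(log_alpha) & (
        np.log(np.maximum(rng.random(rho.size), 1e-300)) < log_alpha
    )
    rho[accept] = prop[accept]


def _block2_update(rho, kappa, lam, layout: _GibbsLayout, rng) -> None:
    """Root-to-tip sweep re-drawing the branch bounds around current VAFs."""
    for inbound, outbound in layout.nodes:
        if inbound < 0:
            min_in = ROOT_LAMBDA
        else:
            idx = layout.muts_on[inbound]
            min_in = float(rho[idx].min()) if idx.size else float(lam[inbound])
        max_out = np.empty(len(outbound))
        for j, c in enumerate(outbound):
            idx = layout.muts_on[c]
            max_out[j] = float(rho[idx].max()) if idx.size else float(kappa[c])
        unalloc = max(min_in - max_out.sum(), 0.0)
        u = np.sort(rng.random(len(outbound) + 1) * unalloc)
        if inbound >= 0 and not layout.is_terminal[inbound]:
            kappa[inbound] = min_in - u[0]
        for j, c in enumerate(outbound):
            lam[c] = max_out[j] + (u[j + 1] - u[j])
        # pinned bounds stay pinned
        for c in outbound:
            if layout.is_terminal[c]:
                kappa[c] = TERMINAL_KAPPA


# ---------------------------------------------------------------------------
# clone fractions and downstream statistics
# ---------------------------------------------------------------------------

def representative_rank(branch_start: float, branch_end: float, cut: float,
                        n_covered: int) -> int:
    """Rank of the covered mutation best representing a clone born at ``cut``.

    For a branch spanning molecular time [start, end] with ``n_covered``
    panel-covered mutations, the cut sits a fraction
    ``f = (cut - start) / (end - start)`` along the branch; the representative
    mutation is the one of rank ``round(f * n_covered)`` (at least 1) when the
    branch's mutations are ordered by decreasing median posterior clonal
    fraction.
    """
    if not branch_start < branch_end:
        raise ValueError("branch must have positive molecular-time span")
    if not branch_start <= cut <= branch_end:
        raise ValueError("cut does not cross this branch")
    if n_covered < 1:
        raise ValueError("branch has no covered mutations")
    f = (cut - branch_start) / (branch_end - branch_start)
    return int(min(n_covered, max(1, np.floor(f * n_covered + 0.5))))


def clone_fractions(
    chain: VafChain,
    tree: Phylogeny,
    cut: float = 100.0,
    clone_min_draws: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Posterior clonal-fraction draws for every clone crossing the cut.

    The molecular-time tree is cut at ``cut`` mutations (measured from the
    zygote); for each branch crossing the cut the representative covered
    mutation is chosen by :func:`representative_rank` and its posterior VAF
    draws doubled (heterozygosity) to give the clone-fraction posterior.
    Branches with no covered mutation inherit the nearest covered ancestor's
    representative and are flagged.
    """
    depth = tree.depths()
    medians = chain.median()
    covered: dict[str, list[str]] = {}
    for m, b in chain.branch_of.items():
        covered.setdefault(b, []).append(m)
    rows = []
    draws: dict[str, np.ndarray] = {}
    mut_index = {m: i for i, m in enumerate(chain.mutation_ids)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        lo, hi = depth[node.parent], depth[node]
        if not (lo < cut <= hi):
            continue
        source, inherited = node, False
        while source is not None and not covered.get(source.name):
            source = source.parent
            inherited = True
        if source is None:  # no covered ancestor anywhere up to the root
            rows.append((f"clone_{node.name}", np.nan, None, True))
            continue
        muts = covered[source.name]
        ordered = sorted(muts, key=lambda m: -medians[m])
        if inherited:
            rank = len(ordered)  # deepest point of the covered ancestor
        else:
            rank = representative_rank(lo, hi, cut, len(ordered))
        rep = ordered[rank - 1]
        clone = f"clone_{node.name}"
        draws[clone] = 2.0 * chain.draws[:, mut_index[rep]]
        rows.append((clone, float(2.0 * medians[rep]), rep, inherited))
    info = pd.DataFrame(rows, columns=["clone", "median_fraction",
                                       "representative", "inherited"])
    return info, draws


def sdi(fraction_draws: dict[str, np.ndarray] | np.ndarray) -> np.ndarray:
    """Posterior draws of the Shannon diversity index over clone fractions.

    Fractions are renormalised per draw to the total captured clonal fraction
    (so p_i is each clone's share of the captured clones); H = -sum p ln p.
    Draws where every fraction is zero give NaN.
    """
    if isinstance(fraction_draws, dict):
        mat = np.column_stack(list(fraction_draws.values()))
    else:
        mat = np.asarray(fraction_draws, dtype=float)
    if mat.ndim == 1:
        mat = mat[None, :]
    totals = mat.sum(axis=1)
    out = np.full(mat.shape[0], np.nan)
    ok = totals > 0
    p = mat[ok] / totals[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    out[ok] = -terms.sum(axis=1)
    return out


def driver_fold_change(
    recipient_draws: np.ndarray,
    donor_draws: np.ndarray,
    censor_floor: float = 1e-6,
) -> dict:
    """Posterior recipient/donor VAF ratio for one driver mutation.

    The retained draws (100 by default) are divided element-wise; the median
    and 95% interval classify the clone as ``higher``/``lower`` in the
    recipient or ``no-difference`` if the interval includes 1.  If the donor
    draws are all ~0 the ratio is flagged right-censored.
    """
    r = np.asarray(recipient_draws, dtype=float)
    d = np.asarray(donor_draws, dtype=float)
    if r.shape != d.shape:
        raise ValueError("draw vectors must have equal length")
    if np.all(d < censor_floor):
        return {"median": np.inf, "lo": np.inf, "hi": np.inf,
                "classification": "higher", "censored": True}
    ratio = r / np.maximum(d, censor_floor)
    lo, med, hi = np.percentile(ratio, [2.5, 50, 97.5])
    if lo > 1:
        cls = "higher"
    elif hi < 1:
        cls = "lower"
    else:
        cls = "no-difference"
    return {"median": float(med), "lo": float(lo), "hi": float(hi),
            "classification": cls, "censored": False}
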