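"""Forward birth-death simulation of haematopoiesis through a transplant.

The simulation starts from a single cell (the donor's zygote), grows the HSC
pool to its target size without death, then maintains it by balanced
birth/death.  Driver mutations enter single cells at a fixed rate per year and
confer a heritable homeostatic selection coefficient S drawn from a gamma
distribution: carriers divide with probability proportional to 1 + S.  At the
age of transplant, ``n_trans`` cells are drawn from the donor pool into a new
recipient compartment under one of three selection models:

* model 1 — uniform sampling (no transplant-specific selection);
* model 2 — sampling weighted by a per-clone engraftment fitness
  S_engraftment ~ Gamma(0.5, 0.5) truncated to [0, 10], with non-driver cells
  weighted at the 30th centile of the drawn values;
* model 3 — uniform sampling, after which a random 10-30% of driver clones in
  the recipient have S multiplied by a factor in [1.5, 7.0] for 5 years.

Both compartments then age independently until the blood draw, when colonies
are sampled uniformly and their genealogy extracted as a time-scaled
:class:`~clonefate.treecore.Phylogeny`.

The stepping kernel is numba-compiled; time advances in fixed steps of
``t_sym / 10`` (0.1 years at the default symmetric-division interval of one
year) with per-step division probabilities scaled accordingly.  During the
developmental growth phase divisions run on a much faster clock
(``growth_division_years``, default 0.1 years) so the pool is established
within the first year or two of life.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .treecore import Node, Phylogeny

__all__ = [
    "SimulationParams",
    "Population",
    "PairSim",
    "simulate_donor",
    "apply_transplant",
    "sample_colonies",
    "simulate_pair",
    "simulate_tcell_lag",
    "prune_to_leaves",
]

_CLONE_CAP = 16384


@dataclass
class SimulationParams:
    """All model-1/2/3 parameters for one donor-recipient pair.

    Defaults describe a realistic sibling pair: transplant at donor age 40,
    sampling 15 years later, an HSC pool of 100,000 cells dividing
    symmetrically about once a year, and roughly two driver mutations entering
    the pool per year with heavy-tailed selection coefficients (mean 2% per
    year).  Reduced-scale analyses pass smaller ``n_hsc`` explicitly.
    """

    n_hsc: int = 100_000
    t_sym: float = 1.0               # years between symmetric divisions
    driver_rate: float = 2.0         # drivers entering the population per year
    gamma_shape: float = 0.5         # S_homeostasis ~ Gamma(shape, rate)
    gamma_rate: float = 25.0
    donor_age_hct: float = 40.0      # years
    donor_age_bd: float = 55.0       # years at blood draw
    n_trans: int = 5_000             # engrafting cells
    model: int = 1
    engraftment_gamma_shape: float = 0.5
    engraftment_gamma_rate: float = 0.5
    engraftment_trunc: tuple[float, float] = (0.0, 10.0)
    nondriver_centile: float = 0.30
    growth_fraction_range: tuple[float, float] = (0.10, 0.30)
    growth_boost_range: tuple[float, float] = (1.5, 7.0)   # S multiplier
    growth_duration: float = 5.0     # years of boosted selection (model 3)
    n_colonies_donor: int = 150
    n_colonies_recipient: int = 150
    growth_division_years: float = 0.1
    dt: float | None = None          # step size; defaults to t_sym / 10

    def __post_init__(self):
        if self.n_hsc < 1:
            raise ValueError("n_hsc must be >= 1")
        if self.n_trans > self.n_hsc:
            raise ValueError("n_trans cannot exceed n_hsc")
        if not (0 < self.donor_age_hct < self.donor_age_bd):
            raise ValueError("require 0 < donor_age_hct < donor_age_bd")
        if min(self.driver_rate, self.gamma_shape, self.gamma_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")

    @property
    def step(self) -> float:
        return self.dt if self.dt is not None else self.t_sym / 10.0


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_phase(parent, ntime, next_node,
               cell_node, cell_clone, n_cells,
               clone_s, clone_mult, clone_parent, clone_ndriv, n_clones,
               t0, t1, dt, t_div, target_n, stop_at_target,
               driver_rate, gamma_shape, gamma_rate):
    """Advance one compartment from t0 to t1.

    Below ``target_n`` no cell dies; at ``target_n`` divisions are matched by
    uniform deaths.  With ``stop_at_target`` the kernel returns as soon as the
    target is reached (used to switch from the developmental growth clock to
    the homeostatic one).  Returns (next_node, n_cells, n_clones, t_reached,
    status): status 0 = reached t1; 1 = node table nearly full; 2 = clone
    table nearly full.  On 1/2 the caller grows the buffers and resumes from
    t_reached.
    """
    t = t0
    cap_nodes = parent.shape[0]
    cap_cells = cell_node.shape[0]
    cap_clones = clone_s.shape[0]
    div_idx = np.empty(cap_cells, np.int64)
    while t < t1 - 1e-12:
        if next_node + 2 * n_cells > cap_nodes:
            return next_node, n_cells, n_clones, t, 1
        if n_clones + 64 > cap_clones:
            return next_node, n_cells, n_clones, t, 2
        step = dt if (t1 - t) > dt else (t1 - t)
        tmid = t + step
        growing = n_cells < target_n
        # --- choose dividing cells ---
        k = 0
        for i in range(n_cells):
            s = clone_s[cell_clone[i]] * clone_mult[cell_clone[i]]
            p = (step / t_div) * (1.0 + s)
            if p > 0.95:
                p = 0.95
            if np.random.random() < p:
                div_idx[k] = i
                k += 1
                if growing and n_cells + k >= target_n:
                    break
        # --- apply divisions (capacity guaranteed by the step-top check) ---
        for j in range(k):
            i = div_idx[j]
            u = cell_node[i]
            parent[next_node] = u
            parent[next_node + 1] = u
            ntime[next_node] = tmid
            ntime[next_node + 1] = tmid
            cell_node[i] = next_node
            cell_node[n_cells] = next_node + 1
            cell_clone[n_cells] = cell_clone[i]
            next_node += 2
            n_cells += 1
        # --- deaths hold the population at target ---
        if not growing:
            while n_cells > target_n:
                r = np.random.randint(n_cells)
                n_cells -= 1
                cell_node[r] = cell_node[n_cells]
                cell_clone[r] = cell_clone[n_cells]
        # --- driver acquisition ---
        # the driver rate is per year at the target population size; scaling
        # by the current size keeps the per-cell rate constant, so the tiny
        # developmental pool is not hit by macroscopic driver clones
        nd = np.random.poisson(driver_rate * step * n_cells / target_n)
        for _ in range(nd):
            if n_clones >= cap_clones:
                break
            i = np.random.randint(n_cells)
            old = cell_clone[i]
            clone_s[n_clones] = clone_s[old] + np.random.gamma(gamma_shape) / gamma_rate
            clone_mult[n_clones] = clone_mult[old]
            clone_parent[n_clones] = old
            clone_ndriv[n_clones] = clone_ndriv[old] + 1
            cell_clone[i] = n_clones
            n_clones += 1
        t = tmid
        if stop_at_target and n_cells >= target_n:
            break
    return next_node, n_cells, n_clones, t, 0


# ---------------------------------------------------------------------------
# python-side state
# ---------------------------------------------------------------------------

class _Genealogy:
    """Append-only node table: parent pointer and node birth time (years)."""

    def __init__(self, capacity: int = 4096):
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.time = np.zeros(capacity, dtype=np.float64)
        self.n_nodes = 1  # node 0 = zygote at time 0

    def ensure(self, extra: int) -> None:
        need = self.n_nodes + extra
        if need > self.parent.shape[0]:
            new_cap = int(need * 1.5) + 1024
            self.parent = np.resize(self.parent, new_cap)
            self.time = np.resize(self.time, new_cap)


def _grown(arr: np.ndarray, new_cap: int, fill) -> np.ndarray:
    out = np.full(new_cap, fill, dtype=arr.dtype)
    out[: arr.shape[0]] = arr
    return out


class _CloneTable:
    """Shared clone registry: selection coefficient, parent clone, driver count."""

    def __init__(self):
        self.s = np.zeros(_CLONE_CAP, dtype=np.float64)
        self.parent = np.full(_CLONE_CAP, -1, dtype=np.int64)
        self.ndriv = np.zeros(_CLONE_CAP, dtype=np.int64)
        self.n_clones = 1  # clone 0 = wild type, S = 0

    @property
    def capacity(self) -> int:
        return self.s.shape[0]

    def grow(self) -> None:
        new_cap = 2 * self.capacity
        self.s = _grown(self.s, new_cap, 0.0)
        self.parent = _grown(self.parent, new_cap, -1)
        self.ndriv = _grown(self.ndriv, new_cap, 0)


class Population:
    """Living cells of one compartment plus the shared coalescent history."""

    def __init__(self, genealogy, clones, cell_node, cell_clone, n_cells, t, params):
        self.genealogy: _Genealogy = genealogy
        self.clones: _CloneTable = clones
        self.cell_node = cell_node
        self.cell_clone = cell_clone
        self.n_cells = int(n_cells)
        self.t = float(t)
        self.params = params
        # per-compartment S multiplier (model-3 boost lives here, not in the
        # shared clone table, so boosting the recipient leaves the donor alone)
        self.mult = np.ones(_CLONE_CAP, dtype=np.float64)

    @property
    def size(self) -> int:
        return self.n_cells

    def clone_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.cell_clone[: self.n_cells], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def driver_clone_fractions(self) -> dict[int, float]:
        """Fraction of cells belonging to each oldest-driver clone lineage."""
        tab = self.clones
        agg: dict[int, int] = {}
        for cid, count in self.clone_counts().items():
            c, top = cid, -1
            while c > 0:
                if tab.ndriv[c] >= 1:
                    top = c
                c = int(tab.parent[c])
            if top >= 0:
                agg[top] = agg.get(top, 0) + count
        return {c: n / self.n_cells for c, n in agg.items()}

    def _run(self, rng, t_end, dt, t_div, target_n, stop_at_target) -> None:
        """Drive the kernel to ``t_end``, growing buffers on capacity yield."""
        p = self.params
        g = self.genealogy
        while True:
            if self.mult.shape[0] < self.clones.capacity:
                self.mult = _grown(self.mult, self.clones.capacity, 1.0)
            _seed_kernel(np.uint32(rng.integers(0, 2**32 - 1)))
            nn, nc, ncl, t, status = _run_phase(
                g.parent, g.time, g.n_nodes,
                self.cell_node, self.cell_clone, self.n_cells,
                self.clones.s, self.mult, self.clones.parent, self.clones.ndriv,
                self.clones.n_clones,
                self.t, t_end, dt, t_div, target_n, stop_at_target,
                p.driver_rate, p.gamma_shape, p.gamma_rate,
            )
            g.n_nodes, self.n_cells, self.clones.n_clones, self.t = nn, nc, ncl, t
            if status == 0 or (stop_at_target and self.n_cells >= target_n):
                return
            if status == 1:
                g.ensure(max(4 * self.n_cells, 1 << 16))
            elif status == 2:
                self.clones.grow()

    def advance(self, t_end: float, target_n: int, seed: int) -> None:
        """Run the birth-death process to ``t_end`` (growth, then homeostasis)."""
        p = self.params
        years = max(t_end - self.t, 0.0)
        if years <= 0:
            return
        max_s = float(self.clones.s[: self.clones.n_clones].max(initial=0.0))
        exp_div = (
            target_n * (years / p.t_sym) * (1.0 + max_s)
            + max(target_n - self.n_cells, 0)
        )
        self.genealogy.ensure(int(2.5 * exp_div) + 4096)
        rng = np.random.default_rng(seed)
        if self.n_cells < target_n:
            self._run(rng, t_end, p.growth_division_years / 10.0,
                      p.growth_division_years, target_n, True)
        if self.t < t_end - 1e-12 and self.n_cells >= target_n:
            self._run(rng, t_end, p.step, p.t_sym, target_n, False)
        self.t = t_end


def _new_population(params: SimulationParams) -> Population:
    cap_cells = 2 * params.n_hsc + 64
    return Population(
        _Genealogy(), _CloneTable(),
        np.zeros(cap_cells, dtype=np.int64), np.zeros(cap_cells, dtype=np.int64),
        n_cells=1, t=0.0, params=params,
    )


# ---------------------------------------------------------------------------
# high-level operations
# ---------------------------------------------------------------------------

def simulate_donor(params: SimulationParams, seed: int | None = None) -> Population:
    """Grow the donor HSC pool from the zygote and age it to the HCT age."""
    rng = np.random.default_rng(seed)
    pop = _new_population(params)
    pop.advance(params.donor_age_hct, params.n_hsc, int(rng.integers(0, 2**31 - 1)))
    return pop


def _weighted_sample_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Efraimidis-Spirakis reservoir keys: the k smallest Exp(1)/w win."""
    w = np.maximum(weights, 1e-300)
    keys = rng.exponential(size=w.size) / w
    return np.argpartition(keys, k - 1)[:k]


def apply_transplant(
    pop: Population, params: SimulationParams, seed: int | None = None
) -> tuple[Population, Population]:
    """Transplant ``n_trans`` cells and age both compartments to the blood draw.

    Selection of the engrafting cells follows ``params.model`` (module
    docstring).  The recipient pool regrows to ``n_hsc`` without death, and
    both compartments then undergo independent homeostatic ageing until
    ``donor_age_bd``.
    """
    p = params
    if p.n_trans > pop.n_cells:
        raise ValueError("n_trans exceeds donor population size")
    if abs(pop.t - p.donor_age_hct) > 1e-9:
        raise ValueError("donor population is not at the HCT age")
    rng = np.random.default_rng(seed)
    n = pop.n_cells
    clones_of_cells = pop.cell_clone[:n]

    if p.model == 2:
        driver_clones = np.unique(
            clones_of_cells[pop.clones.ndriv[clones_of_cells] >= 1]
        )
        if driver_clones.size:
            lo, hi = p.engraftment_trunc
            draws = np.empty(driver_clones.size)
            for i in range(driver_clones.size):
                x = rng.gamma(p.engraftment_gamma_shape, 1.0 / p.engraftment_gamma_rate)
                while not (lo <= x <= hi):
                    x = rng.gamma(p.engraftment_gamma_shape,
                                  1.0 / p.engraftment_gamma_rate)
                draws[i] = x
            base = float(np.quantile(draws, p.nondriver_centile))
            s_eng = np.full(_CLONE_CAP, base)
            s_eng[driver_clones] = draws
            weights = s_eng[clones_of_cells]
        else:
            weights = np.ones(n)
        chosen = _weighted_sample_without_replacement(rng, weights, p.n_trans)
    else:
        chosen = rng.choice(n, size=p.n_trans, replace=False)

    recip = Population(
        pop.genealogy, pop.clones,
        np.zeros(pop.cell_node.shape[0], dtype=np.int64),
        np.zeros(pop.cell_clone.shape[0], dtype=np.int64),
        n_cells=p.n_trans, t=pop.t, params=p,
    )
    recip.cell_node[: p.n_trans] = pop.cell_node[chosen]
    recip.cell_clone[: p.n_trans] = pop.cell_clone[chosen]

    boosted = np.empty(0, dtype=np.int64)
    if p.model == 3:
        rclones = recip.cell_clone[: p.n_trans]
        driver_clones = np.unique(rclones[pop.clones.ndriv[rclones] >= 1])
        if driver_clones.size:
            frac = rng.uniform(*p.growth_fraction_range)
            boosted = driver_clones[rng.random(driver_clones.size) < frac]
            for c in boosted:
                recip.mult[c] = rng.uniform(*p.growth_boost_range)

    seeds = rng.integers(0, 2**31 - 1, size=3)
    if boosted.size:
        t_expire = min(p.donor_age_hct + p.growth_duration, p.donor_age_bd)
        recip.advance(t_expire, p.n_hsc, int(seeds[0]))
        recip.mult[:] = 1.0  # boost expires; S returns to its pre-HCT value
        recip.advance(p.donor_age_bd, p.n_hsc, int(seeds[1]))
    else:
        recip.advance(p.donor_age_bd, p.n_hsc, int(seeds[0]))
    pop.advance(p.donor_age_bd, p.n_hsc, int(seeds[2]))
    return pop, recip


def _extract_tree(
    genealogy: _Genealogy,
    sampled: list[tuple[int, str, str]],
    t_end: float,
    meta: dict,
) -> Phylogeny:
    """Reduce the full genealogy to the coalescent tree of the sampled cells.

    An ancestor is a coalescence of the sample iff sampled lineages reach it
    through at least two distinct children (or it is the current node of two
    or more sampled cells, as can happen when a transplanted cell is sampled
    in both compartments before dividing again).  Internal-node height is the
    time at which the ancestor divided; the zygote roots the tree at height 0.
    """
    parent, time = genealogy.parent, genealogy.time
    arrivals: dict[int, set] = {}
    div_time: dict[int, float] = {}
    for idx, (node_id, _name, _origin) in enumerate(sampled):
        arrivals.setdefault(node_id, set()).add(("leaf", idx))
        div_time.setdefault(node_id, float(time[node_id]))
        u = node_id
        while u != 0:
            child = u
            u = int(parent[child])
            arrivals.setdefault(u, set()).add(("node", child))
            div_time.setdefault(u, float(time[child]))

    retained = {u for u, s in arrivals.items() if len(s) >= 2}
    internal = {u: Node(f"anc_{u}", 0.0) for u in sorted(retained)}
    root = Node("zygote", 0.0)

    def nearest_retained(u: int) -> int | None:
        if u == 0:
            return None
        v = int(parent[u])
        while v != 0 and v not in retained:
            v = int(parent[v])
        return v if v in retained else (0 if 0 in retained else None)

    for u in retained:
        anc = nearest_retained(u)
        node = internal[u]
        if anc is None:
            node.length = div_time[u]
            root.add_child(node)
        else:
            node.length = max(div_time[u] - div_time[anc], 0.0)
            internal[anc].add_child(node)

    for node_id, name, origin in sampled:
        if node_id in retained:
            anc: int | None = node_id
        else:
            anc = nearest_retained(node_id)
        leaf = Node(name)
        leaf.origin = origin
        if anc is None:
            leaf.length = t_end
            root.add_child(leaf)
        else:
            leaf.length = max(t_end - div_time[anc], 0.0)
            internal[anc].add_child(leaf)

    return Phylogeny(root, unit="years", meta=meta)


def sample_colonies(
    donor_pop: Population,
    recipient_pop: Population,
    n_d: int,
    n_r: int,
    seed: int | None = None,
) -> Phylogeny:
    """Sample colonies uniformly from both compartments; return the combined tree.

    Leaves are named ``d###``/``r###`` with origin flags; branch lengths are in
    years and all tips sit at the blood-draw age (ultrametric by construction).
    """
    if n_d > donor_pop.n_cells or n_r > recipient_pop.n_cells:
        raise ValueError("cannot sample more colonies than cells")
    rng = np.random.default_rng(seed)
    t_end = donor_pop.t
    di = rng.choice(donor_pop.n_cells, size=n_d, replace=False) if n_d else []
    ri = rng.choice(recipient_pop.n_cells, size=n_r, replace=False) if n_r else []
    sampled = [(int(donor_pop.cell_node[i]), f"d{k:03d}", "donor")
               for k, i in enumerate(di)]
    sampled += [(int(recipient_pop.cell_node[i]), f"r{k:03d}", "recipient")
                for k, i in enumerate(ri)]
    meta = {
        "sampling_age": t_end,
        "hct_age": donor_pop.params.donor_age_hct,
        "ultrametric": True,
        "leaf_gid": {name: gid for gid, name, _ in sampled},
    }
    return _extract_tree(donor_pop.genealogy, sampled, t_end, meta)


def prune_to_leaves(tree: Phylogeny, names) -> Phylogeny:
    """Restrict a phylogeny to a subset of leaves, suppressing unary nodes.

    Branch lengths (and any branch mutation lists) of merged unary chains are
    concatenated so leaf depths are preserved.
    """
    names = set(names)
    keep: dict[Node, bool] = {}
    for node in tree.postorder():
        keep[node] = (node.name in names) if node.is_leaf else any(
            keep[c] for c in node.children
        )
    if not keep[tree.root]:
        raise ValueError("no leaves retained")
    root = Node(tree.root.name, 0.0)
    for c in tree.root.children:
        if keep[c]:
            root.add_child(_rebuild_pruned(c, keep))
    if not root.children:
        raise ValueError("no leaves retained")
    return Phylogeny(root, unit=tree.unit, meta=dict(tree.meta))


def _rebuild_pruned(node: Node, keep: dict[Node, bool]) -> Node:
    if node.is_leaf:
        out = Node(node.name, node.length, node.origin)
        out.mutations = list(node.mutations)
        return out
    kids = [c for c in node.children if keep[c]]
    if len(kids) == 1:
        child = _rebuild_pruned(kids[0], keep)
        child.length += node.length
        child.mutations = node.mutations + child.mutations
        return child
    out = Node(node.name, node.length, node.origin)
    out.mutations = list(node.mutations)
    for c in kids:
        out.add_child(_rebuild_pruned(c, keep))
    return out


@dataclass
class PairSim:
    """A simulated donor-recipient pair: populations and sampled trees."""

    params: SimulationParams
    donor_pop: Population
    recipient_pop: Population
    combined_tree: Phylogeny
    donor_tree: Phylogeny
    recipient_tree: Phylogeny


def simulate_pair(params: SimulationParams, seed: int | None = None) -> PairSim:
    """Full pipeline: donor ageing, transplant, independent ageing, sampling."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = rng.integers(0, 2**31 - 1, size=3)
    donor = simulate_donor(params, int(s1))
    donor, recip = apply_transplant(donor, params, int(s2))
    combined = sample_colonies(donor, recip, params.n_colonies_donor,
                               params.n_colonies_recipient, int(s3))
    donor_names = [l.name for l in combined.leaves() if l.origin == "donor"]
    recip_names = [l.name for l in combined.leaves() if l.origin == "recipient"]
    donor_tree = prune_to_leaves(combined, donor_names)
    recip_tree = prune_to_leaves(combined, recip_names)
    return PairSim(params, donor, recip, combined, donor_tree, recip_tree)


def simulate_tcell_lag(
    params: SimulationParams,
    lifespan_range: tuple[float, float] = (8.0, 15.0),
    n_sims: int = 100,
    seed: int | None = None,
    expanded_threshold: float = 0.02,
) -> pd.DataFrame:
    """Compare expanded-clone fractions of a lagged vs contemporaneous HSC pool.

    Long-lived T cell clones reflect HSC output from roughly half a lifespan
    before sampling.  Each simulation draws a lifespan L ~ U(8, 15) years, runs
    donor-only ageing, and reads the fraction of cells in expanded driver
    clones (fraction >= ``expanded_threshold``) at age ``donor_age_bd - L/2``
    (lagged; T cell proxy) and at ``donor_age_bd`` (contemporaneous; myeloid
    proxy).  The ratio is NaN when the contemporaneous fraction is 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_sims):
        L = rng.uniform(*lifespan_range)
        t_lag = params.donor_age_bd - L / 2.0
        if t_lag <= 0:
            raise ValueError("donor_age_bd too small for the requested lifespan")
        pop = _new_population(params)
        pop.advance(t_lag, params.n_hsc, int(rng.integers(0, 2**31 - 1)))
        f_lag = _expanded_fraction(pop, expanded_threshold)
        pop.advance(params.donor_age_bd, params.n_hsc,
                    int(rng.integers(0, 2**31 - 1)))
        f_now = _expanded_fraction(pop, expanded_threshold)
        ratio = f_lag / f_now if f_now > 0 else np.nan
        rows.append((L, f_lag, f_now, ratio))
    return pd.DataFrame(
        rows,
        columns=["lifespan", "lagged_fraction", "contemporaneous_fraction", "ratio"],
    )


def _expanded_fraction(pop: Population, threshold: float) -> float:
    fracs = pop.driver_clone_fractions()
    return float(sum(f for f in fracs.values() if f >= threshold))
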