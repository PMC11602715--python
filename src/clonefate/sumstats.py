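"""Tree-derived summary statistics.

Three families of statistics are computed from donor/recipient phylogenies:

* the 13 engraftment statistics summarising a donor-recipient pair of
  time-scaled trees for ABC inference of the engrafting cell number (largest
  clade sizes, singleton counts, coalescence counts in pre-/peri-transplant
  epochs, and the maximum peri-transplant coalescence count within one
  recipient clade — the growth-selection fingerprint);
* the 7 phylogenetic-age statistics for a single molecular-time tree;
* clonal-diversity measures (mean pairwise distance, mean nearest taxon
  distance) and the pruning/growth selection statistics with node-bootstrap
  confidence intervals.

A "clade" is a maximal set of samples sharing a common ancestor after the end
of development; a "singleton" is a sample with no post-development relative
(a clade of size one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treecore import Node, Phylogeny

__all__ = [
    "EpochDefinition",
    "EPOCH_PRESETS",
    "clades_at_cutoff",
    "coalescence_times",
    "engraftment_stats13",
    "phyloage_stats7",
    "mpd",
    "mntd",
    "expanded_clades",
    "pruning_statistic",
    "growth_statistic",
    "pruning_stat",
    "growth_stat",
    "selection_stat_ci",
]

EPOCH_PRESETS = (
    "original",
    "pre_interval_divided",
    "peri_interval_divided",
    "peri_interval_narrower",
    "peri_interval_wider",
)


@dataclass
class EpochDefinition:
    """Pre- and peri-transplant coalescence windows, in years of age.

    The original definition uses one peri-transplant window of duration 10
    years centred on the HCT and one pre-transplant window from age 5 (end of
    development) to the start of the peri window.  The alternative presets
    divide or widen/narrow these windows for sensitivity analysis.
    """

    pre_intervals: list[tuple[float, float]]
    peri_intervals: list[tuple[float, float]]
    preset: str = "original"
    dev_end: float = 5.0

    def __post_init__(self):
        ivals = list(self.pre_intervals) + list(self.peri_intervals)
        for a, b in ivals:
            if b < a:
                raise ValueError(f"interval ({a}, {b}) reversed")
        starts = [a for a, _ in ivals]
        if starts != sorted(starts):
            raise ValueError("epoch intervals must be ordered")

    @classmethod
    def from_preset(cls, preset: str, hct_age: float, dev_end: float = 5.0
                    ) -> "EpochDefinition":
        half = {"original": 5.0, "pre_interval_divided": 5.0,
                "peri_interval_divided": 5.0, "peri_interval_narrower": 2.5,
                "peri_interval_wider": 7.5}
        if preset not in half:
            raise ValueError(f"unknown preset {preset!r}")
        h = half[preset]
        pre = [(dev_end, hct_age - h)]
        peri = [(hct_age - h, hct_age + h)]
        if preset == "pre_interval_divided":
            mid = (dev_end + hct_age - h) / 2.0
            pre = [(dev_end, mid), (mid, hct_age - h)]
        elif preset == "peri_interval_divided":
            peri = [(hct_age - 5.0, hct_age), (hct_age, hct_age + 5.0)]
        return cls(pre, peri, preset=preset, dev_end=dev_end)


# ---------------------------------------------------------------------------
# clade machinery
# ---------------------------------------------------------------------------

def clades_at_cutoff(tree: Phylogeny, cutoff: float) -> list[list[Node]]:
    """Post-development clades: subtrees whose root branch crosses ``cutoff``.

    A node (internal or leaf) founds a clade iff its depth exceeds ``cutoff``
    while its parent's does not; each sample belongs to exactly one clade and
    singletons appear as clades of size one.
    """
    depth = tree.depths()
    clades = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        if depth[node.parent] <= cutoff < depth[node]:
            clades.append(tree.clade_leaves(node))
    # leaves shallower than the cutoff (non-ultrametric edge case)
    assigned = {l for c in clades for l in c}
    for leaf in tree.leaves():
        if leaf not in assigned:
            clades.append([leaf])
    return clades


def coalescence_times(tree: Phylogeny) -> np.ndarray:
    """Depths of all true coalescences (internal nodes with >= 2 children)."""
    depth = tree.depths()
    return np.array([
        depth[n] for n in tree.preorder()
        if not n.is_leaf and len(n.children) >= 2
    ])


def _count_in(times: np.ndarray, interval: tuple[float, float]) -> int:
    a, b = interval
    return int(((times >= a) & (times <= b)).sum())


def _top3(sizes: list[int]) -> list[int]:
    s = sorted(sizes, reverse=True) + [0, 0, 0]
    return s[:3]


# ---------------------------------------------------------------------------
# the 13 engraftment statistics
# ---------------------------------------------------------------------------

def engraftment_stats13(
    donor_tree: Phylogeny,
    recipient_tree: Phylogeny,
    epochs: EpochDefinition,
) -> pd.Series:
    """The engraftment summary-statistic vector for one donor-recipient pair.

    With the original epoch preset this is 13 statistics: (1-3) the three
    largest clade sizes in the donor tree; (4-6) the same for the recipient;
    (7, 8) singleton counts; (9, 10) peri-HCT coalescence counts; (11, 12)
    pre-HCT coalescence counts; (13) the maximum peri-HCT coalescence count
    within a single recipient clade.  Divided-epoch presets produce one count
    per sub-interval and a correspondingly longer vector.

    Both trees must be ultrametric time trees (unit years).
    """
    for t in (donor_tree, recipient_tree):
        if t.unit != "years":
            raise ValueError("engraftment statistics require time trees (years)")
        if not t.meta.get("ultrametric", False):
            raise ValueError("engraftment statistics require ultrametric trees")
    cut = epochs.dev_end
    out: dict[str, float] = {}
    clade_info = {}
    for tag, tree in (("d", donor_tree), ("r", recipient_tree)):
        clades = clades_at_cutoff(tree, cut)
        sizes = _top3([len(c) for c in clades])
        for i, s in enumerate(sizes, start=1):
            out[f"{tag}_clade{i}"] = s
        out_singletons = sum(1 for c in clades if len(c) == 1)
        clade_info[tag] = (tree, clades, out_singletons)
    out["d_singletons"] = clade_info["d"][2]
    out["r_singletons"] = clade_info["r"][2]
    d_times = coalescence_times(donor_tree)
    r_times = coalescence_times(recipient_tree)
    for i, iv in enumerate(epochs.peri_intervals, start=1):
        out[f"d_peri{i}"] = _count_in(d_times, iv)
        out[f"r_peri{i}"] = _count_in(r_times, iv)
    for i, iv in enumerate(epochs.pre_intervals, start=1):
        out[f"d_pre{i}"] = _count_in(d_times, iv)
        out[f"r_pre{i}"] = _count_in(r_times, iv)
    # statistic 13: max peri-HCT coalescences within a single recipient clade
    tree, clades, _ = clade_info["r"]
    depth = tree.depths()
    best = 0
    peri = epochs.peri_intervals
    for clade in clades:
        if len(clade) < 2:
            continue
        names = {l.name for l in clade}
        sub = _subtree_coalescences(tree, names, depth)
        n = sum(_count_in(sub, iv) for iv in peri)
        best = max(best, n)
    out["r_max_clade_peri"] = best
    order = (
        [f"d_clade{i}" for i in (1, 2, 3)] + [f"r_clade{i}" for i in (1, 2, 3)]
        + ["d_singletons", "r_singletons"]
        + [k for i in range(1, len(epochs.peri_intervals) + 1)
           for k in (f"d_peri{i}", f"r_peri{i}")]
        + [k for i in range(1, len(epochs.pre_intervals) + 1)
           for k in (f"d_pre{i}", f"r_pre{i}")]
        + ["r_max_clade_peri"]
    )
    return pd.Series({k: float(out[k]) for k in order})


def _subtree_coalescences(tree: Phylogeny, leaf_names: set[str],
                          depth: dict[Node, float]) -> np.ndarray:
    """Times of coalescences between members of ``leaf_names`` only."""
    counts: dict[Node, int] = {}
    times = []
    for node in tree.postorder():
        if node.is_leaf:
            counts[node] = 1 if node.name in leaf_names else 0
        else:
            child_counts = [counts[c] for c in node.children]
            counts[node] = sum(child_counts)
            if sum(1 for c in child_counts if c > 0) >= 2:
                times.append(depth[node])
    return np.array(times)


# ---------------------------------------------------------------------------
# the 7 phylogenetic-age statistics
# ---------------------------------------------------------------------------

def phyloage_stats7(
    tree: Phylogeny,
    clade_cutoff: float = 50.0,
    expanded_min_samples: int = 3,
) -> pd.Series:
    """Summary statistics for phylogenetic-age ABC on one molecular-time tree.

    (1-3) the three largest clade sizes (clades: common ancestor after
    ``clade_cutoff`` mutations, i.e. post-embryonic development); (4) the
    singleton count; (5-6) coalescence counts in the 20-40th and 40-60th
    height-centile bins; (7) the proportion of samples inside expanded clades
    (clades with >= ``expanded_min_samples`` samples).
    """
    clades = clades_at_cutoff(tree, clade_cutoff)
    sizes = [len(c) for c in clades]
    top = _top3(sizes)
    n_leaves = len(tree.leaves())
    times = coalescence_times(tree)
    depth = tree.depths()
    height = max(depth[l] for l in tree.leaves())
    b1 = _count_in(times, (0.2 * height, 0.4 * height))
    b2 = _count_in(times, (0.4 * height, 0.6 * height))
    expanded = sum(s for s in sizes if s >= expanded_min_samples)
    return pd.Series({
        "clade1": float(top[0]), "clade2": float(top[1]), "clade3": float(top[2]),
        "singletons": float(sum(1 for s in sizes if s == 1)),
        "coal_20_40": float(b1), "coal_40_60": float(b2),
        "expanded_prop": expanded / n_leaves,
    })


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def mpd(tree: Phylogeny) -> float:
    """Mean pairwise (cophenetic) distance over all unordered leaf pairs."""
    _, dist = tree.cophenetic()
    n = dist.shape[0]
    if n < 2:
        raise ValueError("MPD needs at least 2 leaves")
    iu = np.triu_indices(n, k=1)
    return float(dist[iu].mean())


def mntd(tree: Phylogeny) -> float:
    """Mean nearest-taxon distance: mean over leaves of the smallest non-zero
    cophenetic distance in that leaf's row."""
    _, dist = tree.cophenetic()
    n = dist.shape[0]
    if n < 2:
        raise ValueError("MNTD needs at least 2 leaves")
    mins = []
    for i in range(n):
        row = dist[i][dist[i] > 0]
        if row.size:
            mins.append(row.min())
    return float(np.mean(mins))


def expanded_clades(
    fractions: dict[str, float],
    threshold: float = 0.02,
    drivers: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Clones whose clonal fraction reaches ``threshold`` of haematopoiesis."""
    drivers = drivers or {}
    rows = [
        (clone, frac, drivers.get(clone))
        for clone, frac in sorted(fractions.items(), key=lambda kv: -kv[1])
        if frac >= threshold
    ]
    return pd.DataFrame(rows, columns=["clone", "fraction", "driver"])


# ---------------------------------------------------------------------------
# pruning / growth selection statistics
# ---------------------------------------------------------------------------

def pruning_statistic(n_pre_r: int, n_r: int, n_pre_d: int, n_d: int) -> float:
    """((1 + n_pre,R) / (1 + N_R)) / ((1 + n_pre,D) / (1 + N_D)).

    One is added to every count so the statistic is defined even when a clade
    is absent from one tree.  The growth variant has identical form with
    peri-HCT counts.
    """
    return ((1.0 + n_pre_r) / (1.0 + n_r)) / ((1.0 + n_pre_d) / (1.0 + n_d))


growth_statistic = pruning_statistic  # same functional form, peri-HCT counts


def _clade_times(tree: Phylogeny, clade_leaf_names) -> np.ndarray:
    depth = tree.depths()
    names = set(clade_leaf_names)
    if len(names) < 2:
        return np.empty(0)
    return _subtree_coalescences(tree, names, depth)


def pruning_stat(
    donor_tree: Phylogeny,
    recipient_tree: Phylogeny,
    donor_clade,
    recipient_clade,
    epochs: EpochDefinition,
) -> float:
    """Pruning selection statistic for one expanded clade.

    ``donor_clade``/``recipient_clade`` are the clade's leaf names in each
    tree (empty if the clade was not sampled there — counts are then 0 and the
    +1 guard keeps the statistic defined).  Pre-HCT coalescences are those in
    the epochs' pre-transplant window(s).
    """
    tr = _clade_times(recipient_tree, recipient_clade)
    td = _clade_times(donor_tree, donor_clade)
    n_pre_r = sum(_count_in(tr, iv) for iv in epochs.pre_intervals)
    n_pre_d = sum(_count_in(td, iv) for iv in epochs.pre_intervals)
    return pruning_statistic(n_pre_r, tr.size, n_pre_d, td.size)


def growth_stat(
    donor_tree: Phylogeny,
    recipient_tree: Phylogeny,
    donor_clade,
    recipient_clade,
    epochs: EpochDefinition,
) -> float:
    """Growth selection statistic: as pruning, but peri-HCT coalescences."""
    tr = _clade_times(recipient_tree, recipient_clade)
    td = _clade_times(donor_tree, donor_clade)
    n_peri_r = sum(_count_in(tr, iv) for iv in epochs.peri_intervals)
    n_peri_d = sum(_count_in(td, iv) for iv in epochs.peri_intervals)
    return pruning_statistic(n_peri_r, tr.size, n_peri_d, td.size)


def selection_stat_ci(
    recipient_times: np.ndarray,
    donor_times: np.ndarray,
    window_intervals,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Node-bootstrap percentile interval for a pruning/growth statistic.

    The clade's coalescence times are resampled with replacement within each
    tree; the statistic is recomputed per bootstrap and the
    ``alpha/2``/``1 - alpha/2`` percentiles returned.
    """
    rng = np.random.default_rng(seed)
    rt = np.asarray(recipient_times, dtype=float)
    dt = np.asarray(donor_times, dtype=float)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        r = rng.choice(rt, size=rt.size, replace=True) if rt.size else rt
        d = rng.choice(dt, size=dt.size, replace=True) if dt.size else dt
        nr = sum(_count_in(r, iv) for iv in window_intervals)
        nd = sum(_count_in(d, iv) for iv in window_intervals)
        stats[b] = pruning_statistic(nr, r.size, nd, d.size)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
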