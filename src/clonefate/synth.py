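"""Synthetic-data generation: full truth scenarios for every pipeline stage.

A :class:`TruthScenario` bundles a simulated donor-recipient pair with the
downstream products the real study would derive from sequencing: a combined
mutation-annotated molecular-time phylogeny (somatic SNVs accumulating at 15.8
per year plus ~60 at birth), true per-branch VAFs for each compartment and
mature cell type, optional APOBEC-like mutation bursts on recipient
post-transplant branches, colony-level read counts at ~11.5x with injected
impure and duplicate colonies, and deep targeted counts at ~1,720x with
matched control samples for error-rate estimation.

Everything is reproducible from the seed recorded in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readcounts import ReadCountMatrix, TargetedCounts
from .simulator import PairSim, SimulationParams, simulate_pair
from .treecore import Node, Phylogeny

__all__ = [
    "TruthScenario",
    "molecular_clock_tree",
    "make_scenario",
    "emit_colony_reads",
    "emit_targeted_reads",
]

DEFAULT_RATE = 15.8       # somatic SNVs per HSPC per year in adult life
DEFAULT_BIRTH_BURDEN = 60.0   # SNVs present at birth
DEV_YEARS = 0.5           # the birth burden is spread over this initial window


def molecular_clock_tree(
    tree: Phylogeny,
    rate_per_year: float = DEFAULT_RATE,
    birth_burden: float = DEFAULT_BIRTH_BURDEN,
    seed: int | None = None,
    mutation_prefix: str = "m",
    assign_ids: bool = True,
) -> Phylogeny:
    """Overlay a somatic molecular clock on a time tree.

    Each branch receives ``Poisson(rate * years)`` mutations, plus a share of
    ``Poisson(birth_burden)`` for the portion of the branch overlapping the
    developmental window [0, 0.5] years.  Branch lengths become mutation
    counts (unit "mutations"); mutation ids are recorded per branch.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    depth = out.depths()
    counter = 0
    for node in out.preorder():
        if node.parent is None:
            continue
        t0, t1 = depth[node.parent], depth[node]
        overlap = max(0.0, min(t1, DEV_YEARS) - min(t0, DEV_YEARS))
        mu = rate_per_year * (t1 - t0) + birth_burden * overlap / DEV_YEARS
        n = int(rng.poisson(mu))
        node.length = float(n)
        if assign_ids:
            node.mutations = [f"{mutation_prefix}{counter + i:06d}" for i in range(n)]
            counter += n
    out.unit = "mutations"
    out.meta.pop("ultrametric", None)
    return out


@dataclass
class TruthScenario:
    """Ground truth for one synthetic donor-recipient pair."""

    params: SimulationParams
    seed: int
    pair: PairSim
    combined_molecular: Phylogeny       # mutation-annotated, unit=mutations
    donor_molecular: Phylogeny
    recipient_molecular: Phylogeny
    true_vaf: dict                      # (compartment, cell_type) -> {branch: rho}
    sporadic: dict[str, int]            # APOBEC/platinum spike counts per branch
    cell_types: tuple[str, ...]
    manifest: dict = field(default_factory=dict)

    def branch_mutations(self) -> dict[str, list[str]]:
        return {n.name: list(n.mutations)
                for n in self.combined_molecular.preorder() if n.parent is not None}


def _population_clade_fractions(pair: PairSim) -> dict[str, dict[str, float]]:
    """Fraction of each compartment's cells descending from each tree branch.

    Sampled-tree internal nodes are named ``anc_<gid>`` after their genealogy
    node; every living cell's ancestor path is intersected with those nodes.
    Mutations on a branch are given the clonal fraction of the branch's child
    end (mutations arise along the branch; using the child clade is the
    conservative end of the span).
    """
    tree = pair.combined_tree
    gid_of: dict[int, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        if node.name.startswith("anc_"):
            gid_of[int(node.name[4:])] = node.name
    leaf_gid = tree.meta.get("leaf_gid", {})
    for name, gid in leaf_gid.items():
        gid_of.setdefault(int(gid), name)

    out: dict[str, dict[str, float]] = {}
    for comp, pop in (("donor", pair.donor_pop), ("recipient", pair.recipient_pop)):
        parent = pop.genealogy.parent
        counts: dict[str, int] = {}
        n = pop.n_cells
        for i in range(n):
            u = int(pop.cell_node[i])
            while u >= 0:
                name = gid_of.get(u)
                if name is not None:
                    counts[name] = counts.get(name, 0) + 1
                u = int(parent[u]) if u != 0 else -1
        out[comp] = {name: c / n for name, c in counts.items()}
    return out


def make_scenario(
    pair_config: SimulationParams,
    seed: int = 0,
    cell_types: tuple[str, ...] = ("gran", "mono", "B", "T"),
    rate_per_year: float = DEFAULT_RATE,
    birth_burden: float = DEFAULT_BIRTH_BURDEN,
    lineage_bias_sd: float = 0.5,
    apobec_fraction: float = 0.02,
    apobec_burden: tuple[int, int] = (200, 2000),
) -> TruthScenario:
    """Simulate a pair and derive its full downstream truth.

    ``lineage_bias_sd`` is the log-normal s.d. of per-driver-clone,
    per-cell-type output biases (clones often skew toward one mature lineage);
    biases are applied at clone level so the true VAFs still nest along the
    tree.  A fraction of recipient terminal branches receives an APOBEC-like
    burst of extra mutations, recorded in ``sporadic`` for the
    branch-shortening step.
    """
    rng = np.random.default_rng(seed)
    pair = simulate_pair(pair_config, int(rng.integers(0, 2**31 - 1)))
    combined_mol = molecular_clock_tree(
        pair.combined_tree, rate_per_year, birth_burden,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # APOBEC-like sporadic bursts on recipient terminal branches
    sporadic: dict[str, int] = {}
    recip_leaves = [l for l in combined_mol.leaves() if l.origin == "recipient"]
    n_spike = int(round(apobec_fraction * len(recip_leaves)))
    if n_spike:
        idx = rng.choice(len(recip_leaves), size=n_spike, replace=False)
        for i in idx:
            leaf = recip_leaves[i]
            extra = int(rng.integers(*apobec_burden))
            leaf.mutations = leaf.mutations + [
                f"apo_{leaf.name}_{j:04d}" for j in range(extra)
            ]
            leaf.length += extra
            sporadic[leaf.name] = extra

    # population-truth clonal fractions, with per-cell-type lineage bias;
    # the wobble is a single multiplicative factor per (compartment, cell
    # type) applied to every clade fraction — per-branch factors would break
    # the nesting that the Gibbs sampler relies on
    base_frac = _population_clade_fractions(pair)
    true_vaf: dict = {}
    for comp in ("donor", "recipient"):
        for ct in cell_types:
            wob = float(np.exp(rng.normal(0.0, lineage_bias_sd)))
            fracs = {}
            for name, f in base_frac[comp].items():
                fracs[name] = min(0.5, 0.5 * min(1.0, f * wob))
            true_vaf[(comp, ct)] = fracs
    manifest = {"seed": int(seed), "rate_per_year": rate_per_year,
                "birth_burden": birth_burden, "cell_types": list(cell_types),
                "apobec_fraction": apobec_fraction}
    donor_names = [l.name for l in combined_mol.leaves() if l.origin == "donor"]
    recip_names = [l.name for l in combined_mol.leaves() if l.origin == "recipient"]
    from .simulator import prune_to_leaves

    return TruthScenario(
        params=pair_config, seed=seed, pair=pair,
        combined_molecular=combined_mol,
        donor_molecular=prune_to_leaves(combined_mol, donor_names),
        recipient_molecular=prune_to_leaves(combined_mol, recip_names),
        true_vaf=true_vaf, sporadic=sporadic, cell_types=cell_types,
        manifest=manifest,
    )


def _presence_matrix(tree: Phylogeny) -> tuple[list[str], list[str], np.ndarray]:
    """(mutation ids, leaf names, presence[mut, leaf]) from branch mutations."""
    leaves = tree.leaves()
    leaf_index = {l.name: i for i, l in enumerate(leaves)}
    mut_ids: list[str] = []
    rows = []
    for node in tree.preorder():
        if node.parent is None or not node.mutations:
            continue
        clade = [leaf_index[l.name] for l in tree.clade_leaves(node)]
        row = np.zeros(len(leaves), dtype=np.int8)
        row[clade] = 1
        for m in node.mutations:
            mut_ids.append(m)
            rows.append(row)
    presence = np.vstack(rows) if rows else np.zeros((0, len(leaves)), dtype=np.int8)
    return mut_ids, [l.name for l in leaves], presence


def _well_of(i: int) -> str:
    return f"{chr(ord('A') + (i // 12) % 8)}{i % 12 + 1:02d}"


def emit_colony_reads(
    scenario: TruthScenario,
    depth: float = 11.5,
    impure_fraction: float = 0.05,
    duplicate_fraction: float = 0.03,
    seed: int | None = None,
) -> tuple[ReadCountMatrix, dict]:
    """Binomial colony-level WGS read counts with QC challenges injected.

    Depths are Poisson(``depth``); variant reads are Binomial(depth,
    0.5 * purity * presence) where a random ``impure_fraction`` of colonies
    are 50:50-ish mixtures with another colony of the same individual (purity
    ~ U(0.45, 0.6)).  A ``duplicate_fraction`` of colonies is emitted twice
    into adjacent wells (the technical-duplicate failure mode).  Returns the
    count matrix and a truth dict naming the injected impure colonies and
    duplicate pairs.
    """
    rng = np.random.default_rng(seed)
    tree = scenario.combined_molecular
    mut_ids, leaf_names, presence = _presence_matrix(tree)
    origin = {l.name: l.origin for l in tree.leaves()}
    n_mut, n_leaf = presence.shape

    purity = np.ones(n_leaf)
    partner = np.full(n_leaf, -1)
    n_impure = int(round(impure_fraction * n_leaf))
    impure_idx = rng.choice(n_leaf, size=n_impure, replace=False) if n_impure else []
    same_side = {
        s: [j for j, n in enumerate(leaf_names) if origin[n] == s]
        for s in ("donor", "recipient")
    }
    # contaminant = a clonally unrelated colony of the same individual: a
    # mixture with a near-identical sibling is effectively still clonal and
    # is not the failure mode the purity filter is meant to catch
    shared = (presence.astype(np.int32).T @ presence.astype(np.int32))
    own = np.diag(shared)
    for i in impure_idx:
        purity[i] = rng.uniform(0.45, 0.55)
        pool = np.array([j for j in same_side[origin[leaf_names[i]]] if j != i])
        overlap = shared[i, pool] / np.maximum(own[i], 1)
        distant = pool[overlap < 0.5]
        partner[i] = rng.choice(distant if distant.size else pool)

    p_present = 0.5 * purity[None, :] * presence
    mixed = partner >= 0
    if mixed.any():
        p_present[:, mixed] += (
            0.5 * (1.0 - purity[mixed])[None, :] * presence[:, partner[mixed]]
        )

    names = list(leaf_names)
    cols_p = [p_present]
    dup_pairs = []
    n_dup = int(round(duplicate_fraction * n_leaf))
    dup_idx = rng.choice(n_leaf, size=n_dup, replace=False) if n_dup else []
    for i in dup_idx:
        dup_name = f"{leaf_names[i]}_dup"
        names.append(dup_name)
        cols_p.append(p_present[:, [i]])
        dup_pairs.append((leaf_names[i], dup_name))
    P = np.clip(np.concatenate(cols_p, axis=1), 0.0, 1.0)

    dep = rng.poisson(depth, size=P.shape).astype(np.int32)
    var = rng.binomial(dep, P).astype(np.int32)

    # well assignment: row-major per individual, each duplicate placed in the
    # well right after its original (adjacent, as picked colonies would be)
    origin_all = {**origin, **{d: origin[o] for o, d in dup_pairs}}
    per_ind_counter = {"donor": 0, "recipient": 0}
    wells = {}
    for name in names:
        if name.endswith("_dup"):
            continue
        side = origin_all[name]
        wells[name] = _well_of(per_ind_counter[side])
        per_ind_counter[side] += 1
        dup_name = f"{name}_dup"
        if dup_name in names:
            wells[dup_name] = _well_of(per_ind_counter[side])
            per_ind_counter[side] += 1

    sample_meta = pd.DataFrame({
        "origin": [origin_all[n] for n in names],
        "well": [wells[n] for n in names],
    }, index=names)
    mutation_meta = pd.DataFrame({"is_xy": np.zeros(n_mut, dtype=bool)},
                                 index=mut_ids)
    counts = ReadCountMatrix(
        pd.DataFrame(var, index=mut_ids, columns=names),
        pd.DataFrame(dep, index=mut_ids, columns=names),
        mutation_meta, sample_meta,
    )
    truth = {
        "impure": [leaf_names[i] for i in impure_idx],
        "duplicates": dup_pairs,
        "purity": dict(zip(leaf_names, purity)),
    }
    return counts, truth


def emit_targeted_reads(
    scenario: TruthScenario,
    depth: float = 1720.0,
    panel_fraction: float = 0.6,
    n_controls: int = 3,
    error_log_mean: float = np.log(3e-4),
    error_log_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[TargetedCounts, pd.DataFrame, dict]:
    """Deep targeted read counts for every compartment and cell type.

    A random ``panel_fraction`` of each branch's mutations enters the capture
    panel.  For each bulk sample (``<compartment>_<cell type>``) variant reads
    follow Binomial(N, pi(rho_true, eps)) at Poisson(``depth``) coverage with
    per-site error rates drawn log-normally.  Control samples (individuals
    without the mutations, rho = 0) are returned separately for error-rate
    estimation.  Also returns the truth mapping of mutation -> true VAF per
    sample.
    """
    rng = np.random.default_rng(seed)
    tree = scenario.combined_molecular
    branch_of: dict[str, str] = {}
    panel: list[str] = []
    for node in tree.preorder():
        if node.parent is None or not node.mutations:
            continue
        take = rng.random(len(node.mutations)) < panel_fraction
        if node.mutations and not take.any():
            take[rng.integers(len(node.mutations))] = True  # cover every branch
        for m, t in zip(node.mutations, take):
            if t:
                panel.append(m)
                branch_of[m] = node.name
    eps = {m: float(min(0.05, np.exp(rng.normal(error_log_mean, error_log_sd))))
           for m in panel}

    rows = []
    truth: dict[str, dict[str, float]] = {}
    for (comp, ct), fracs in scenario.true_vaf.items():
        sample = f"{comp}_{ct}"
        truth[sample] = {}
        for m in panel:
            rho = float(fracs.get(branch_of[m], 0.0))
            truth[sample][m] = rho
            N = int(rng.poisson(depth))
            pi = rho + eps[m] - 2 * rho * eps[m]
            Y = int(rng.binomial(N, pi)) if N else 0
            rows.append((m, sample, Y, N))
    counts = TargetedCounts(
        pd.DataFrame(rows, columns=["mutation_id", "sample", "variant", "depth"]),
        error_rates=eps, branch_of=branch_of,
        is_xy={m: False for m in panel},
    )
    ctl_rows = []
    for c in range(n_controls):
        for m in panel:
            N = int(rng.poisson(depth))
            Y = int(rng.binomial(N, eps[m])) if N else 0
            ctl_rows.append((m, f"control_{c}", Y, N))
    controls = pd.DataFrame(ctl_rows,
                            columns=["mutation_id", "sample", "variant", "depth"])
    return counts, controls, truth
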