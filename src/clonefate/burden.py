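"""Mutation-burden utilities: clock conversion, corrected burdens, prevalence.

Somatic SNVs accumulate clock-like at ~15.8 per HSPC per year during adult
life, so an excess mutation burden converts directly into years of apparent
extra ageing.  Corrected burdens sum sensitivity-corrected ancestral branch
lengths from the root to each colony.
"""

from __future__ import annotations

import pandas as pd

from .treecore import Phylogeny, SensitivityProfile, correct_branch_lengths

__all__ = [
    "MUTATION_RATE_PER_YEAR",
    "excess_burden_years",
    "signature_prevalence",
    "corrected_snv_burden",
]

MUTATION_RATE_PER_YEAR = 15.8


def excess_burden_years(excess_mutations: float,
                        rate_per_year: float = MUTATION_RATE_PER_YEAR) -> float:
    """Convert an excess SNV burden into equivalent years of normal ageing."""
    if rate_per_year <= 0:
        raise ValueError("rate must be positive")
    return excess_mutations / rate_per_year


def signature_prevalence(n_with: int, n_total: int) -> float:
    """Percentage of colonies carrying a feature (e.g. an APOBEC burst)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with <= n_total:
        raise ValueError("n_with must be between 0 and n_total")
    return 100.0 * n_with / n_total


def corrected_snv_burden(tree: Phylogeny,
                         profile: SensitivityProfile | None = None) -> pd.Series:
    """Per-colony SNV burden: the sum of (corrected) ancestral branch lengths.

    With a sensitivity profile the branch lengths are corrected first (private
    branches by 1/p_i, shared branches by 1/(1 - prod(1 - p_i))).
    """
    t = correct_branch_lengths(tree, profile) if profile is not None else tree
    depth = t.depths()
    return pd.Series({l.name: depth[l] for l in t.leaves()}, dtype=float)
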