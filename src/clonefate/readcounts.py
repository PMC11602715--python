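"""Read-count containers shared by colony QC, mutation assignment and the
Gibbs sampler.

A :class:`ReadCountMatrix` holds variant/total read depths for every mutation
in every sample (colony-level WGS at ~11x, or deep targeted bulk counts), plus
mutation and sample metadata.  Serialised as TSV with paired
``<sample>.var`` / ``<sample>.dep`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReadCountMatrix", "TargetedCounts"]


@dataclass
class ReadCountMatrix:
    """Mutations x samples grid of (variant_reads, total_depth).

    ``variant`` and ``depth`` are DataFrames indexed by mutation id with one
    column per sample; ``mutation_meta`` may carry chrom/pos/ref/alt and an
    ``is_xy`` flag; ``sample_meta`` may carry individual, donor/recipient
    origin and plate well.
    """

    variant: pd.DataFrame
    depth: pd.DataFrame
    mutation_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if not self.variant.index.equals(self.depth.index) or list(
            self.variant.columns
        ) != list(self.depth.columns):
            raise ValueError("variant and depth matrices must be aligned")
        if (self.variant.to_numpy() > self.depth.to_numpy()).any():
            raise ValueError("variant reads exceed total depth somewhere")
        if (self.variant.to_numpy() < 0).any() or (self.depth.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def mutations(self) -> list[str]:
        return list(self.variant.index)

    @property
    def samples(self) -> list[str]:
        return list(self.variant.columns)

    def variant_matrix(self, samples=None) -> np.ndarray:
        cols = samples if samples is not None else self.samples
        return self.variant[cols].to_numpy(dtype=float)

    def depth_matrix(self, samples=None) -> np.ndarray:
        cols = samples if samples is not None else self.samples
        return self.depth[cols].to_numpy(dtype=float)

    def vaf(self) -> pd.DataFrame:
        dep = self.depth.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(dep > 0, self.variant.to_numpy(dtype=float) / dep, np.nan)
        return pd.DataFrame(v, index=self.variant.index, columns=self.variant.columns)

    def subset(self, mutations=None, samples=None) -> "ReadCountMatrix":
        v, d = self.variant, self.depth
        mm, sm = self.mutation_meta, self.sample_meta
        if mutations is not None:
            v, d = v.loc[mutations], d.loc[mutations]
            if not mm.empty:
                mm = mm.loc[mutations]
        if samples is not None:
            v, d = v[samples], d[samples]
            if not sm.empty:
                sm = sm.loc[samples]
        return ReadCountMatrix(v, d, mm, sm)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        wide = pd.concat(
            {"var": self.variant, "dep": self.depth}, axis=1
        ).swaplevel(axis=1)
        wide.columns = [f"{s}.{k}" for s, k in wide.columns]
        wide.sort_index(axis=1).to_csv(path, sep="\t", index_label="mutation_id")

    @classmethod
    def from_tsv(cls, path) -> "ReadCountMatrix":
        wide = pd.read_csv(path, sep="\t", index_col="mutation_id")
        var_cols = [c for c in wide.columns if c.endswith(".var")]
        samples = [c[:-4] for c in var_cols]
        variant = wide[[f"{s}.var" for s in samples]]
        depth = wide[[f"{s}.dep" for s in samples]]
        variant.columns = samples
        depth.columns = samples
        return cls(variant, depth)


@dataclass
class TargetedCounts:
    """Deep targeted read counts per mutation per bulk cell fraction.

    ``counts`` is a long DataFrame with columns
    ``mutation_id, sample, variant, depth``; ``error_rates`` maps mutation id
    to the per-site sequencing error estimated from control individuals;
    ``branch_of`` maps mutation id to its branch on the phylogeny; ``is_xy``
    flags sex-chromosome mutations (depth doubling in males).
    """

    counts: pd.DataFrame
    error_rates: dict[str, float] = field(default_factory=dict)
    branch_of: dict[str, str] = field(default_factory=dict)
    is_xy: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        required = {"mutation_id", "sample", "variant", "depth"}
        if not required <= set(self.counts.columns):
            raise ValueError(f"counts must have columns {sorted(required)}")
        if (self.counts["variant"] > self.counts["depth"]).any():
            raise ValueError("variant reads exceed depth")

    @property
    def samples(self) -> list[str]:
        return sorted(self.counts["sample"].unique())

    def for_sample(self, sample: str) -> pd.DataFrame:
        sub = self.counts[self.counts["sample"] == sample]
        return sub.set_index("mutation_id")[["variant", "depth"]]

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out["error_rate"] = out["mutation_id"].map(self.error_rates).fillna(0.0)
        out["branch_id"] = out["mutation_id"].map(self.branch_of)
        out["is_xy"] = out["mutation_id"].map(self.is_xy).fillna(False)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TargetedCounts":
        df = pd.read_csv(path, sep="\t")
        err = (
            df.drop_duplicates("mutation_id").set_index("mutation_id")["error_rate"].to_dict()
            if "error_rate" in df.columns else {}
        )
        branch = (
            df.drop_duplicates("mutation_id").set_index("mutation_id")["branch_id"].to_dict()
            if "branch_id" in df.columns else {}
        )
        xy = (
            df.drop_duplicates("mutation_id").set_index("mutation_id")["is_xy"].to_dict()
            if "is_xy" in df.columns else {}
        )
        keep = [c for c in ("mutation_id", "sample", "variant", "depth") if c in df.columns]
        return cls(df[keep], error_rates=err, branch_of=branch, is_xy=xy)
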