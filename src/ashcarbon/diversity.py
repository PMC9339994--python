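"""ASV/OTU-table summaries: alpha diversity, phylum abundance, Venn regions.

The container is a sample x taxon count table with per-sample treatment
metadata and a taxon -> phylum taxonomy ("ASV" and "OTU" are the same
abstraction here). Estimators follow the conventions of the QIIME2 alpha
stack: Shannon in bits (log2), bias-corrected Chao1
(S_obs + F1(F1-1) / (2(F2+1))) and Good's coverage 1 - F1/N, all on raw
(unrarefied) integer counts. An optional even-depth subsampler is provided
for sensitivity checks but is never applied implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio.diversity import alpha as skbio_alpha

from . import stats as treatment_stats

__all__ = [
    "AsvTable",
    "alpha_diversity",
    "phylum_abundance",
    "venn_counts",
    "diversity_property_correlations",
    "rarefy",
]


@dataclass
class AsvTable:
    """Sample x taxon counts with metadata and phylum-level taxonomy.

    ``counts``: integer DataFrame, rows = sample ids, columns = taxon ids.
    ``metadata``: DataFrame indexed like ``counts`` with ``treatment`` and
    ``replicate`` columns.
    ``taxonomy``: Series mapping every taxon id to a phylum name (missing
    assignments are filled with ``"Unclassified"``).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata must index the same samples")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero samples are not allowed")
        self.taxonomy = self.taxonomy.reindex(self.counts.columns).fillna("Unclassified")

    # -- TSV round trip (QIIME2-export dialect: features x samples) --------

    def to_tsv(self, table_path, taxonomy_path, metadata_path) -> None:
        feat = self.counts.T
        feat.index.name = "#OTU ID"
        feat.to_csv(table_path, sep="\t")
        tax = self.taxonomy.rename("phylum").to_frame()
        tax.index.name = "feature"
        tax.to_csv(taxonomy_path, sep="\t")
        md = self.metadata.copy()
        md.index.name = "sample"
        md.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, table_path, taxonomy_path, metadata_path) -> "AsvTable":
        feat = pd.read_csv(table_path, sep="\t", index_col=0)
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)["phylum"]
        md = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts=feat.T, metadata=md, taxonomy=tax)


def _require_integer(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("chao1 and Good's coverage need raw integer counts")
    return np.round(arr).astype(np.int64)


def alpha_diversity(table: AsvTable, shannon_base: float = 2.0) -> pd.DataFrame:
    """Per-sample observed features, Chao1, Shannon and Good's coverage.

    Shannon defaults to bits (base 2); pass ``shannon_base=np.e`` for nats.
    """
    arr = _require_integer(table.counts)
    rows = []
    for sample, counts in zip(table.counts.index, arr):
        rows.append(
            {
                "sample": sample,
                "observed_features": int(skbio_alpha.sobs(counts)),
                "chao1": float(skbio_alpha.chao1(counts, bias_corrected=True)),
                "shannon": float(skbio_alpha.shannon(counts, base=shannon_base)),
                "goods_coverage": float(skbio_alpha.goods_coverage(counts)),
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    return out.join(table.metadata)


def phylum_abundance(table: AsvTable) -> dict[str, pd.DataFrame]:
    """Relative phylum abundances per sample and per treatment.

    Sample-level proportions are counts summed within phylum over the sample
    total (each row sums to 1); treatment-level values are the means of the
    replicate proportions.
    """
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty sample")
    by_phylum = table.counts.T.groupby(table.taxonomy).sum().T
    per_sample = by_phylum.div(totals, axis=0)
    per_treatment = per_sample.groupby(table.metadata["treatment"], sort=False).mean()
    return {"per_sample": per_sample, "per_treatment": per_treatment}


def venn_counts(table: AsvTable, group: str = "treatment") -> dict[str, int]:
    """Region counts of the presence/absence Venn over treatment groups.

    A feature is present in a group when its summed count over that group's
    samples is > 0. Returns a dict keyed by "&"-joined sorted group subsets
    (all 2^k - 1 regions) plus ``"total"`` = features present anywhere.
    """
    labels = table.metadata[group]
    group_names = list(dict.fromkeys(labels))
    present = {
        g: table.counts.loc[labels == g].sum(axis=0) > 0 for g in group_names
    }
    membership = pd.DataFrame(present)
    regions: dict[str, int] = {}
    for k in range(1, len(group_names) + 1):
        for combo in combinations(group_names, k):
            inside = membership[list(combo)].all(axis=1)
            outside = membership[[g for g in group_names if g not in combo]].any(axis=1)
            regions["&".join(combo)] = int((inside & ~outside).sum())
    regions["total"] = int(membership.any(axis=1).sum())
    return regions


def diversity_property_correlations(
    alpha: pd.DataFrame, pools: pd.DataFrame, properties: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Pearson correlations between alpha-diversity indices and soil pools.

    ``alpha`` is the output of :func:`alpha_diversity`; ``pools`` must carry
    ``treatment`` and ``replicate`` so samples can be matched. Delegates to
    :func:`ashcarbon.stats.correlation_matrix`.
    """
    idx_cols = ["treatment", "replicate"]
    merged = alpha.reset_index().merge(pools, on=idx_cols, validate="one_to_one")
    indices = ["observed_features", "chao1", "shannon", "goods_coverage"]
    if properties is None:
        properties = [
            c
            for c in pools.columns
            if c not in idx_cols and np.issubdtype(pools[c].dtype, np.number)
        ]
    sub = merged[indices + properties]
    # constant indices (e.g. saturated richness) carry no correlation signal
    sub = sub.loc[:, sub.std(ddof=1) > 0]
    return treatment_stats.correlation_matrix(sub)


def rarefy(table: AsvTable, depth: int, seed: int = 0) -> AsvTable:
    """Subsample every sample to an even depth without replacement.

    Samples shallower than ``depth`` are rejected. Intended for sensitivity
    checks only; the default pipeline works on raw counts.
    """
    arr = _require_integer(table.counts)
    if (arr.sum(axis=1) < depth).any():
        raise ValueError(f"every sample needs >= {depth} reads to rarefy")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(arr)
    for i, row in enumerate(arr):
        reads = np.repeat(np.arange(row.size), row)
        picked = rng.choice(reads, size=depth, replace=False)
        out[i] = np.bincount(picked, minlength=row.size)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return AsvTable(counts=counts, metadata=table.metadata.copy(), taxonomy=table.taxonomy.copy())
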