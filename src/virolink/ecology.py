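"""Abundance, activity, diversity and environment-correlation statistics.

Conventions follow the virome read-mapping workflow the package models:
per-entity coverage is summed mapped read length divided by genome length,
rescaled by library size for cross-sample comparison (reference = mean
library by default); an entity is present (metagenome) or active
(metatranscriptome) in a sample when its mapped read length exceeds 10% of
its genome length (strict >); gene expression uses a modified TPM,
count * (1000 / gene length) * (1e6 / library size), after zeroing
singleton counts; alpha diversity is richness and natural-log Shannon;
beta diversity is Bray-Curtis. Genome-vs-environment association uses
per-entity Pearson correlations against each measured groundwater
variable with no multiple-testing correction by default, plus a host-virus
pair "co-correlation" verdict (both members significant for the same
variable with the same sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def normalized_coverage(
    mapped_lengths: pd.DataFrame,
    entity_lengths: Mapping[str, int],
    library_sizes: Mapping[str, float],
    reference: float | None = None,
) -> pd.DataFrame:
    """Per-entity, per-sample coverage table.

    mapped_lengths needs columns entity_id, sample_id, mapped_bp (summed
    mapped read length; for multi-contig bins, summed over contigs, with
    entity_lengths the summed contig length). Adds raw_cov = mapped_bp /
    entity_length and norm_cov = raw_cov * (reference_library /
    sample_library); reference defaults to the mean library size.
    """
    df = mapped_lengths.copy()
    unknown = set(df["entity_id"]) - set(entity_lengths)
    if unknown:
        raise KeyError(f"entities without lengths: {sorted(unknown)[:5]}")
    unknown_s = set(df["sample_id"]) - set(library_sizes)
    if unknown_s:
        raise KeyError(f"samples without library sizes: {sorted(unknown_s)[:5]}")
    lengths = df["entity_id"].map(entity_lengths).astype(float)
    if (lengths <= 0).any():
        raise ValueError("entity lengths must be positive")
    libs = df["sample_id"].map(library_sizes).astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    ref = float(np.mean(list(library_sizes.values()))) if reference is None else reference
    df["raw_cov"] = df["mapped_bp"] / lengths
    df["norm_cov"] = df["raw_cov"] * ref / libs
    return df


def coverage_matrix(cov: pd.DataFrame, value: str = "norm_cov") -> pd.DataFrame:
    """Wide entity x sample matrix from a coverage table (missing -> 0)."""
    return cov.pivot_table(
        index="entity_id", columns="sample_id", values=value, fill_value=0.0, aggfunc="sum"
    )


def presence_activity(
    mapped_bp: float | np.ndarray, entity_length: float, threshold: float = 0.10
):
    """Present/active call: mapped read length strictly exceeds `threshold`
    of the genome length (exactly 10% is absent)."""
    if entity_length <= 0:
        raise ValueError("entity_length must be positive")
    return np.asarray(mapped_bp) / entity_length > threshold


def presence_table(
    mapped_lengths: pd.DataFrame, entity_lengths: Mapping[str, int], threshold: float = 0.10
) -> pd.DataFrame:
    """Wide boolean entity x sample presence/activity matrix."""
    df = mapped_lengths.copy()
    lengths = df["entity_id"].map(entity_lengths).astype(float)
    df["present"] = df["mapped_bp"].to_numpy() / lengths.to_numpy() > threshold
    return df.pivot_table(
        index="entity_id", columns="sample_id", values="present", fill_value=False, aggfunc="any"
    ).astype(bool)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def tpm_modified(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    library_sizes: Mapping[str, float],
    drop_singletons: bool = True,
) -> pd.DataFrame:
    """Modified TPM: count * (1000 / gene length) * (1e6 / library size).

    Singleton counts (exactly 1 read) are zeroed before normalization when
    drop_singletons is set. counts needs columns gene_id, sample_id,
    read_count.
    """
    df = counts.copy()
    lengths = df["gene_id"].map(gene_lengths).astype(float)
    if lengths.isna().any():
        raise KeyError("genes without lengths in counts table")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libs = df["sample_id"].map(library_sizes).astype(float)
    counts_eff = df["read_count"].astype(float).copy()
    if drop_singletons:
        counts_eff[df["read_count"] == 1] = 0.0
    df["tpm_mod"] = counts_eff * (1000.0 / lengths) * (1e6 / libs)
    return df


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


def alpha_diversity(matrix: pd.DataFrame, presence: pd.DataFrame | None = None) -> pd.DataFrame:
    """Richness and natural-log Shannon index per sample.

    matrix is entity x sample abundance (non-negative). Richness counts
    entities present (from the optional boolean presence matrix, else
    abundance > 0); Shannon H = -sum p ln p over relative abundances.
    All-zero samples get richness 0 and H 0 with a warning.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    rows = []
    for sample in matrix.columns:
        x = matrix[sample].to_numpy(dtype=float)
        total = x.sum()
        if presence is not None and sample in presence.columns:
            richness = int(presence[sample].sum())
        else:
            richness = int((x > 0).sum())
        if total == 0:
            warnings.warn(f"sample {sample}: all-zero abundances; Shannon reported as 0")
            h = 0.0
        else:
            p = x[x > 0] / total
            h = float(-np.sum(p * np.log(p)))
        rows.append({"sample_id": sample, "richness": richness, "shannon": h})
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity from an entity x sample
    abundance matrix. Pairs of all-zero samples are reported as 0 with a
    warning (the dissimilarity is undefined there)."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    data = matrix.to_numpy(dtype=float).T  # samples x entities
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(data, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s): Bray-Curtis undefined, reported as 0")
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Environment correlations
# ---------------------------------------------------------------------------


def env_correlations(
    matrix: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every entity's normalized coverage against
    every environmental parameter.

    matrix is entity x sample; env is sample x parameter (missing values
    excluded pairwise). Returns long table (entity_id, parameter, n, r, p,
    significant). Zero-variance vectors are excluded with a warning.
    bh_correct applies Benjamini-Hochberg across the whole screen (off by
    default: each test is judged at alpha alone).
    """
    samples = [s for s in matrix.columns if s in env.index]
    rows = []
    for entity in matrix.index:
        x_all = matrix.loc[entity, samples].to_numpy(dtype=float)
        for param in env.columns:
            y_all = env.loc[samples, param].to_numpy(dtype=float)
            mask = ~np.isnan(x_all) & ~np.isnan(y_all)
            if mask.sum() < 3:
                continue
            x, y = x_all[mask], y_all[mask]
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero-variance vector for ({entity}, {param}); correlation skipped"
                )
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                {"entity_id": entity, "parameter": param, "n": int(mask.sum()), "r": r, "p": p}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def pair_cocorrelation(
    correlations: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    matrix: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Host-virus pair verdicts: a pair co-correlates with a parameter iff
    both members are significant (p < alpha) with the same sign of r.

    When the abundance matrix is supplied, a host-vs-virus abundance
    regression (slope, r, p) is reported per pair as well.
    """
    sig = correlations[correlations["p"] < alpha]
    rows = []
    for virus, host in pairs:
        v = sig[sig["entity_id"] == virus].set_index("parameter")["r"]
        h = sig[sig["entity_id"] == host].set_index("parameter")["r"]
        shared = [
            param
            for param in v.index.intersection(h.index)
            if np.sign(v[param]) == np.sign(h[param])
        ]
        row = {
            "virus_id": virus,
            "host_id": host,
            "co_correlated_parameters": ",".join(sorted(shared)),
            "n_co_correlated": len(shared),
        }
        if matrix is not None and virus in matrix.index and host in matrix.index:
            x = matrix.loc[host].to_numpy(dtype=float)
            y = matrix.loc[virus].to_numpy(dtype=float)
            if np.std(x) > 0 and np.std(y) > 0:
                res = stats.linregress(x, y)
                row.update(
                    pair_slope=res.slope, pair_r=res.rvalue, pair_p=res.pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows)
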