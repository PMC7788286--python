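"""AP-MS interactome filtering: bait-IP vs IgG enrichment with
missing-not-at-random imputation and cross-condition consensus.

The pipeline consumes a log2 LFQ intensity matrix (proteins x IP samples,
missing values explicit) with per-protein peptide counts and sample labels
(condition = cell line x treatment; group = bait-IP vs IgG). Per condition:

1. abundance filters — at least ``min_peptides`` peptides per protein and at
   least ``min_valid_in_bait`` observed values in the bait-IP group;
2. Gaussian-downshift imputation — missing entries of each column are drawn
   from Normal(mu_obs - downshift * sigma_obs, (width * sigma_obs)^2), the
   standard model for low-abundance missing-not-at-random dropout (defaults
   width 0.2, downshift 1.8);
3. moderated t of bait vs IgG with BH adjustment; adj p < 0.1 marks the
   per-condition "significantly enriched" tier.

Consensus interactors are the proteins with adj p below the (stricter)
consensus threshold, default 0.05, in every required condition; a
user-supplied known-interactor list labels each consensus protein known or
novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import substream
from .stats import bh_adjust, moderated_t

__all__ = [
    "IntensityMatrix",
    "ImputeParams",
    "filter_proteins",
    "impute_downshift",
    "impute_matrix",
    "enrich_vs_igg",
    "intersect_conditions",
    "simulate_apms",
]

GROUPS = ("bait", "IgG")


@dataclass
class IntensityMatrix:
    """Protein x IP-sample log2 LFQ intensities with an explicit missing-value
    mask (NaN), per-protein peptide counts, and sample labels."""

    intensities: pd.DataFrame  # protein x sample, NaN = missing
    peptide_counts: pd.Series  # per protein
    labels: pd.DataFrame  # sample -> condition, group, replicate

    def __post_init__(self):
        self.peptide_counts = self.peptide_counts.reindex(self.intensities.index)
        if self.peptide_counts.isna().any():
            raise ValueError("peptide_counts missing for some proteins")
        if (self.peptide_counts < 0).any():
            raise ValueError("peptide_counts must be >= 0")
        need = {"condition", "group"}
        if not need <= set(self.labels.columns):
            raise ValueError(f"labels need columns {sorted(need)}")
        missing = set(self.intensities.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)}")
        bad = set(self.labels["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)} (expected {GROUPS})")
        for cond, grp in self.labels.groupby("condition"):
            if set(grp["group"]) != set(GROUPS):
                raise ValueError(f"condition {cond!r} lacks a bait or IgG group")

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.labels["condition"]))

    def samples(self, condition: str, group: str | None = None) -> list:
        lab = self.labels[self.labels["condition"] == condition]
        if group is not None:
            lab = lab[lab["group"] == group]
        return [s for s in lab.index if s in self.intensities.columns]

    def subset(self, proteins=None, samples=None) -> "IntensityMatrix":
        ints = self.intensities
        if proteins is not None:
            ints = ints.loc[proteins]
        if samples is not None:
            ints = ints[samples]
        return IntensityMatrix(ints, self.peptide_counts.reindex(ints.index),
                               self.labels.loc[list(ints.columns)])

    def write_tsv(self, intensities_path, labels_path) -> None:
        out = self.intensities.copy()
        out.insert(0, "peptide_count", self.peptide_counts)
        out.to_csv(intensities_path, sep="\t", index_label="protein_id")
        self.labels.to_csv(labels_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, intensities_path, labels_path) -> "IntensityMatrix":
        df = pd.read_csv(intensities_path, sep="\t", index_col="protein_id")
        pep = df.pop("peptide_count")
        labels = pd.read_csv(labels_path, sep="\t", index_col="sample_id")
        return cls(df, pep, labels)


@dataclass(frozen=True)
class ImputeParams:
    """Gaussian-downshift imputation parameters (Perseus-style): imputed
    distribution is Normal(mu - downshift*sigma, (width*sigma)^2) per column."""

    width: float = 0.2
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self):
        if self.width < 0 or self.downshift < 0:
            raise ValueError("width and downshift must be >= 0")


def filter_proteins(
    m: IntensityMatrix,
    condition: str,
    min_peptides: int = 2,
    min_valid_in_bait: int = 3,
) -> IntensityMatrix:
    """Retain proteins with >= min_peptides peptides and >= min_valid_in_bait
    observed (non-missing) intensities in the condition's bait-IP group."""
    bait = m.samples(condition, "bait")
    if not bait:
        raise ValueError(f"condition {condition!r} has no bait samples")
    n_valid = m.intensities[bait].notna().sum(axis=1)
    keep = (m.peptide_counts >= min_peptides) & (n_valid >= min_valid_in_bait)
    return m.subset(proteins=m.intensities.index[keep])


def impute_downshift(
    column: pd.Series,
    p: ImputeParams = ImputeParams(),
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Fill one sample column's missing values from the downshifted Gaussian.

    mu_obs and sigma_obs are the column's observed mean and standard
    deviation (ddof=1); observed entries are untouched. Deterministic given
    the rng/seed. With width 0 every imputed value is exactly
    mu_obs - downshift * sigma_obs.
    """
    col = column.astype(float).copy()
    miss = col.isna()
    if not miss.any():
        return col
    obs = col[~miss]
    if obs.size < 2:
        raise ValueError(
            f"column {column.name!r}: needs >= 2 observed values to impute"
        )
    mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    col[miss] = rng.normal(mu - p.downshift * sigma, p.width * sigma, size=int(miss.sum()))
    return col


def impute_matrix(
    m: IntensityMatrix,
    p: ImputeParams = ImputeParams(),
    samples: list | None = None,
) -> IntensityMatrix:
    """Column-wise downshift imputation over ``samples`` (default: all), with
    one named substream per column so results are order-independent and
    reproducible from the single seed."""
    ints = m.intensities.copy()
    for s in samples if samples is not None else list(ints.columns):
        ints[s] = impute_downshift(ints[s], p, rng=substream(p.seed, "impute", s))
    return IntensityMatrix(ints, m.peptide_counts, m.labels)


def enrich_vs_igg(
    m: IntensityMatrix,
    condition: str,
    impute: ImputeParams | None = ImputeParams(),
    min_peptides: int = 2,
    min_valid_in_bait: int = 3,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-condition enrichment table: filter, impute, moderated t of bait-IP
    vs IgG, BH adjust. ``significant`` flags the 10% FDR tier."""
    f = filter_proteins(m, condition, min_peptides, min_valid_in_bait)
    cond_samples = f.samples(condition)
    f = f.subset(samples=cond_samples)
    if impute is not None:
        f = impute_matrix(f, impute)
    bait = f.samples(condition, "bait")
    igg = f.samples(condition, "IgG")
    if len(bait) < 2 or len(igg) < 2:
        raise ValueError(f"condition {condition!r}: both groups need >= 2 samples")
    if f.intensities.isna().any().any():
        raise ValueError("missing values remain; imputation required before testing")
    res = moderated_t(f.intensities, test=bait, reference=igg)
    res = res.rename(columns={"log_fc": "log_enrichment"})
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    res["significant"] = res["adj_p"] < fdr
    res.attrs["condition"] = condition
    return res


def intersect_conditions(
    per_condition: dict,
    required: list | None = None,
    consensus_p: float = 0.05,
    known_interactors=None,
) -> pd.DataFrame:
    """Consensus interactors across conditions.

    A protein is a consensus interactor when adj_p < consensus_p in every
    required condition. ``known_interactors`` (iterable of protein ids, e.g.
    a reference interaction list loaded from TSV) sets the novelty flag.
    Returns one row per protein seen in any required condition with columns
    adj_p_<cond>, log_enrichment_<cond>, consensus, novel.
    """
    required = list(required) if required is not None else list(per_condition)
    missing = [c for c in required if c not in per_condition]
    if missing:
        raise ValueError(f"missing required conditions: {missing}")
    known = set(known_interactors) if known_interactors is not None else set()
    proteins = sorted(set().union(*[set(per_condition[c].index) for c in required]))
    out = pd.DataFrame(index=pd.Index(proteins, name="protein_id"))
    consensus = pd.Series(True, index=out.index)
    for c in required:
        tab = per_condition[c]
        out[f"log_enrichment_{c}"] = tab["log_enrichment"].reindex(proteins)
        out[f"adj_p_{c}"] = tab["adj_p"].reindex(proteins)
        ok = (tab["adj_p"] < consensus_p) & (tab["log_enrichment"] > 0)
        consensus &= ok.reindex(proteins, fill_value=False).astype(bool)
    out["consensus"] = consensus
    out["novel"] = consensus & ~out.index.isin(known)
    return out


def load_known_interactors(path) -> set:
    """Read a one-column (or first-column) TSV of known interactor ids."""
    df = pd.read_csv(path, sep="\t")
    return set(df.iloc[:, 0].astype(str))


# ---------------------------------------------------------------------------
# Synthetic AP-MS generator
# ---------------------------------------------------------------------------

def simulate_apms(
    n_proteins: int = 1000,
    n_interactors: int = 30,
    n_conditions: int = 4,
    n_replicates: int = 4,
    enrichment_log2: float = 3.0,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.0,
    within_sd: float = 0.5,
    dropout_steepness: float = 1.5,
    dropout_midpoint_quantile: float = 0.12,
    seed: int = 0,
):
    """Synthetic AP-MS experiment with planted bait interactors.

    Per-protein baseline log2 intensities are Normal(baseline_mean,
    baseline_sd^2); the first ``n_interactors`` proteins gain
    ``enrichment_log2`` in bait-IP samples. Measurement noise is
    Normal(0, within_sd^2). Missingness is missing-not-at-random: the dropout
    probability is a logistic function of the realized intensity, centered at
    the ``dropout_midpoint_quantile`` quantile of all intensities, so
    low-abundance measurements (background binders, and interactors on the
    IgG side) go missing preferentially. Peptide counts scale with baseline
    abundance (>= 1 for all but a few low-abundance proteins).

    Returns ``(IntensityMatrix, truth: Series of planted-interactor flags)``.
    """
    rng = substream(seed, "apms")
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    planted = pd.Series(
        [i < n_interactors for i in range(n_proteins)],
        index=proteins, name="planted",
    )
    baseline = rng.normal(baseline_mean, baseline_sd, n_proteins)
    pep = np.maximum(
        0, np.round((baseline - baseline.min()) / 2.0 + rng.poisson(2, n_proteins))
    ).astype(int)

    cols, rows = {}, []
    for ci in range(1, n_conditions + 1):
        cond = f"cond{ci}"
        for group in GROUPS:
            for rep in range(1, n_replicates + 1):
                sid = f"{cond}_{group}_r{rep}"
                srng = substream(seed, "apms", sid)
                x = baseline + srng.normal(0.0, within_sd, n_proteins)
                if group == "bait":
                    x = x + np.where(planted.to_numpy(), enrichment_log2, 0.0)
                cols[sid] = x
                rows.append({"sample_id": sid, "condition": cond,
                             "group": group, "replicate": rep})
    ints = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))
    flat = ints.to_numpy().ravel()
    mid = np.quantile(flat, dropout_midpoint_quantile)
    p_miss = 1.0 / (1.0 + np.exp(dropout_steepness * (ints.to_numpy() - mid)))
    mask = substream(seed, "apms", "mask").random(p_miss.shape) < p_miss
    ints = ints.mask(mask)
    labels = pd.DataFrame(rows).set_index("sample_id")
    m = IntensityMatrix(ints, pd.Series(pep, index=proteins), labels)
    return m, planted
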