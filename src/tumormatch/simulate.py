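"""Synthetic tumor / cell-line cohort generator with known ground truth.

Emulates the statistical structure of a bulk RNA-seq comparison between
primary tumors and cancer cell lines of one tumor type:

* each tumor is a purity-weighted mixture, on the linear (count-expectation)
  scale, of a subtype-specific cancer profile and a shared immune/stromal
  contamination profile, with purity drawn from a Beta distribution;
* cell lines are pure cancer profiles with an extra up-shift on a
  proliferation gene module (the in-vitro culturing signal);
* a fraction of tumor samples carries an additive per-gene platform (batch)
  shift on the log scale;
* counts are negative-binomial around the mixed expectation with log-normal
  per-sample library-size factors.

Every generated object carries a :class:`SyntheticTruth` so downstream
stages (purity adjustment, differential expression, subtype classification)
can be validated against known gene roles, purities and subtype labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_gene_sets",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model.

    Effect sizes are in log2 units; ``subtype_logfc=2`` means marker genes
    are 4-fold elevated in their subtype's cancer profile.
    """

    n_genes: int = 2000
    n_tumors: int = 100
    n_cell_lines: int = 30
    n_subtypes: int = 3
    n_marker_genes_per_subtype: int = 30
    subtype_logfc: float = 2.0
    n_immune_genes: int = 150
    immune_logfc: float = 3.0
    purity_beta_a: float = 5.0
    purity_beta_b: float = 2.0
    n_proliferation_genes: int = 50
    proliferation_logfc: float = 1.0
    batch_fraction: float = 0.3
    batch_sd: float = 0.5
    nb_dispersion: float = 0.1
    libsize_logsd: float = 0.3
    seed: int = 0
    tumor_type: str = "T01"
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tumors": self.n_tumors,
            "n_cell_lines": self.n_cell_lines,
            "n_subtypes": self.n_subtypes,
            "n_marker_genes_per_subtype": self.n_marker_genes_per_subtype,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_immune_genes < 0 or self.n_proliferation_genes < 0:
            raise ValueError("gene-module sizes must be non-negative")
        if self.purity_beta_a <= 0 or self.purity_beta_b <= 0:
            raise ValueError("purity Beta shape parameters must be > 0")
        if not 0.0 <= self.batch_fraction <= 1.0:
            raise ValueError("batch_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        special = (
            self.n_subtypes * self.n_marker_genes_per_subtype
            + self.n_immune_genes
            + self.n_proliferation_genes
        )
        if special > self.n_genes:
            raise ValueError(
                f"marker+immune+proliferation genes ({special}) exceed n_genes "
                f"({self.n_genes})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``gene_roles`` maps every gene to exactly one role:
    ``marker:<subtype>``, ``immune``, ``proliferation`` or ``background``.
    """

    purity: pd.Series
    subtype: pd.Series
    batch: pd.Series
    gene_roles: pd.Series
    config: SyntheticConfig = field(repr=False, default=None)
    library_factor: pd.Series = field(repr=False, default=None)
    expected_counts: pd.DataFrame = field(repr=False, default=None)

    def marker_genes(self, subtype: str) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == f"marker:{subtype}"])

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == role])

    @property
    def subtype_names(self) -> list[str]:
        roles = self.gene_roles[self.gene_roles.str.startswith("marker:")]
        return sorted({r.split(":", 1)[1] for r in roles})


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def expected_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Deterministic pieces of the model for a given config.

    Returns ``(cancer_profiles, roles_frame, immune_profile, baseline)``
    where ``cancer_profiles`` has one linear-scale column per subtype.
    Reproduces exactly the profiles :func:`generate_cohort` uses, so tests
    can check simulated means against the closed-form mixture.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    baseline_log2 = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )

    roles = np.array(["background"] * config.n_genes, dtype=object)
    cursor = 0
    subtype_names = [f"S{k + 1}" for k in range(config.n_subtypes)]
    for name in subtype_names:
        roles[cursor : cursor + config.n_marker_genes_per_subtype] = f"marker:{name}"
        cursor += config.n_marker_genes_per_subtype
    roles[cursor : cursor + config.n_immune_genes] = "immune"
    cursor += config.n_immune_genes
    roles[cursor : cursor + config.n_proliferation_genes] = "proliferation"
    # positions are then shuffled so roles are not block-ordered in the output
    perm = rng.permutation(config.n_genes)
    roles = roles[perm]

    # contaminating (immune/stromal) profile: immune genes elevated; cancer
    # profiles: immune genes depressed by the same amount, since immune
    # transcripts come from infiltrating cells and are essentially absent
    # from pure cancer-cell populations
    is_immune = roles == "immune"
    immune_log2 = baseline_log2 + np.where(is_immune, config.immune_logfc, 0.0)
    cancer = {}
    for name in subtype_names:
        shift = np.where(roles == f"marker:{name}", config.subtype_logfc, 0.0)
        shift = shift - np.where(is_immune, config.immune_logfc, 0.0)
        cancer[name] = 2.0 ** (baseline_log2 + shift)
    cancer_profiles = pd.DataFrame(cancer, index=genes)
    immune_profile = pd.Series(2.0**immune_log2, index=genes, name="immune")
    roles_series = pd.Series(roles, index=genes, name="role")
    return cancer_profiles, roles_series, immune_profile, pd.Series(
        baseline_log2, index=genes, name="baseline_log2"
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort: counts (genes x samples), metadata, truth.

    Fully deterministic given ``config.seed``. The count expectation of
    tumor sample *s* with purity ``p`` is ``lib_s * (p * C_g + (1-p) * I_g)``
    (times the log-normal batch factor for second-platform samples), where
    ``C`` is the sample's subtype cancer profile and ``I`` the contamination
    profile; cell lines have expectation ``lib_s * C_g`` with proliferation
    genes multiplied by ``2**proliferation_logfc``.
    """
    config.validate()
    cancer_profiles, roles, immune_profile, baseline = expected_expression(config)
    # independent stream for the stochastic draws; profile stream above is
    # consumed identically by expected_expression so both stay in sync
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = list(cancer_profiles.index)
    subtype_names = list(cancer_profiles.columns)

    tumor_ids = _sample_ids("TUM", config.n_tumors)
    cl_ids = _sample_ids("CL", config.n_cell_lines)

    purity = pd.Series(
        rng.beta(config.purity_beta_a, config.purity_beta_b, config.n_tumors),
        index=tumor_ids,
        name="purity",
    )
    tumor_subtypes = pd.Series(
        [subtype_names[i % len(subtype_names)] for i in range(config.n_tumors)],
        index=tumor_ids,
    )
    cl_subtypes = pd.Series(
        [subtype_names[i % len(subtype_names)] for i in range(config.n_cell_lines)],
        index=cl_ids,
    )

    n_batch2 = int(round(config.batch_fraction * config.n_tumors))
    batch2_idx = rng.choice(config.n_tumors, size=n_batch2, replace=False)
    batch = pd.Series("platformA", index=tumor_ids + cl_ids, name="batch")
    batch.iloc[batch2_idx] = "platformB"
    batch_shift_log2 = rng.normal(0.0, config.batch_sd, config.n_genes)

    # libsize_logsd is the SD of natural-log library factors, mean 0
    lib = pd.Series(
        np.exp(rng.normal(0.0, config.libsize_logsd, config.n_tumors + config.n_cell_lines)),
        index=tumor_ids + cl_ids,
    )

    C = cancer_profiles.to_numpy()  # genes x subtypes
    I = immune_profile.to_numpy()
    sub_index = {name: j for j, name in enumerate(subtype_names)}

    # sequencing is compositional: reads are sampled in proportion to the
    # relative abundance of each gene, so each sample's mean vector is
    # rescaled to a common total before the library factor is applied
    # (contamination dilutes cancer transcripts instead of adding depth)
    target_total = float((2.0 ** baseline.to_numpy()).sum())

    mean = np.empty((config.n_genes, config.n_tumors + config.n_cell_lines))
    for s, sid in enumerate(tumor_ids):
        p = purity.iloc[s]
        mu = p * C[:, sub_index[tumor_subtypes.iloc[s]]] + (1.0 - p) * I
        if batch.loc[sid] == "platformB":
            mu = mu * 2.0**batch_shift_log2
        mean[:, s] = mu / mu.sum() * target_total * lib.loc[sid]
    prolif_mult = np.where(
        roles.to_numpy() == "proliferation", 2.0**config.proliferation_logfc, 1.0
    )
    for s, sid in enumerate(cl_ids):
        mu = C[:, sub_index[cl_subtypes.iloc[s]]] * prolif_mult
        mean[:, config.n_tumors + s] = mu / mu.sum() * target_total * lib.loc[sid]

    counts = _negative_binomial(rng, mean, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=tumor_ids + cl_ids)

    metadata = pd.DataFrame(
        {
            "sample_id": tumor_ids + cl_ids,
            "cohort": ["tumor"] * config.n_tumors + ["cell_line"] * config.n_cell_lines,
            "tumor_type": config.tumor_type,
            "purity": [purity[t] for t in tumor_ids] + [np.nan] * config.n_cell_lines,
            "batch": [batch[s] for s in tumor_ids + cl_ids],
            "subtype": list(tumor_subtypes) + list(cl_subtypes),
        }
    ).set_index("sample_id", drop=False)

    truth = SyntheticTruth(
        purity=purity,
        subtype=pd.concat([tumor_subtypes, cl_subtypes]).rename("subtype"),
        batch=batch,
        gene_roles=roles,
        config=config,
        library_factor=lib,
        expected_counts=pd.DataFrame(mean, index=genes, columns=tumor_ids + cl_ids),
    )
    return counts_df, metadata, truth


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + disp*mu^2)."""
    if dispersion == 0.0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_gene_sets(
    truth: SyntheticTruth,
    n_random_sets: int = 0,
    set_size: int = 50,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene sets implied by the truth, plus optional random background sets.

    Always emits the immune module, the proliferation module and one marker
    set per subtype; random sets are uniform draws from all genes. The
    result is GMT-serializable via :func:`tumormatch.io.write_gmt`.
    """
    all_genes = list(truth.gene_roles.index)
    if set_size >= len(all_genes):
        raise ValueError("set_size must be smaller than the number of genes")
    sets: dict[str, list[str]] = {
        "IMMUNE_MODULE": truth.genes_with_role("immune"),
        "PROLIFERATION_MODULE": truth.genes_with_role("proliferation"),
    }
    for name in truth.subtype_names:
        sets[f"MARKERS_{name}"] = truth.marker_genes(name)
    rng = np.random.default_rng(seed)
    for i in range(n_random_sets):
        members = rng.choice(all_genes, size=set_size, replace=False)
        sets[f"RANDOM_{i + 1:03d}"] = sorted(members)
    return sets


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
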