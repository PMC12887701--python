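"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration (including the seed)
and also returns a machine-readable truth object sufficient to score every
downstream recovery test.  Summary-statistic noise follows the
standardized-trait approximation SE = 1/sqrt(2*MAF*(1-MAF)*n), which makes
the Steiger variance-explained computation exact under the generative model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import split_rng


class ConfigurationError(ValueError):
    """A generator configuration field is invalid; the message names it."""


# non-palindromic allele pairs only: the generator never emits A/T or C/G
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class GwasSimConfig:
    """Parameters of a two-sample summary-statistic simulation."""

    n_instruments: int = 50
    beta_causal: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    het_sd: float = 0.0
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 1
    ld_r2: float = 0.0
    gamma_range: tuple[float, float] = (0.05, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if self.n_instruments < 2:
            raise ConfigurationError(f"n_instruments must be >= 2, got {self.n_instruments}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0 <= self.ld_r2 <= 1:
            raise ConfigurationError(f"ld_r2 must be in [0, 1], got {self.ld_r2}")
        if self.ld_block_size < 1:
            raise ConfigurationError(f"ld_block_size must be >= 1, got {self.ld_block_size}")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigurationError("n_exposure and n_outcome must be >= 2")
        if self.het_sd < 0:
            raise ConfigurationError(f"het_sd must be >= 0, got {self.het_sd}")


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta) / se
    p = 2.0 * stats.norm.sf(z)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_gwas_pair(cfg: GwasSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an (exposure, outcome) summary-statistic pair plus LD matrix.

    Per-SNP true exposure effects gamma_j are drawn from ``gamma_range`` with
    random sign; the outcome true effect is
    ``(beta_causal + eta_j) * gamma_j + alpha_j`` with eta_j ~ N(0, het_sd)
    (per-SNP causal-effect noise) and alpha_j ~ N(pleiotropy_mean,
    pleiotropy_sd) (direct, InSIDE-violating pleiotropy when the mean is
    nonzero).  Estimated betas add N(0, se) noise with the standardized SE
    model; the LD matrix is block-diagonal with constant ``ld_r2``
    off-diagonals inside blocks of ``ld_block_size``.
    """
    cfg.validate()
    m = cfg.n_instruments
    rng = split_rng(cfg.seed, "gwas_pair")

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    gamma = rng.uniform(cfg.gamma_range[0], cfg.gamma_range[1], size=m)
    gamma *= rng.choice([-1.0, 1.0], size=m)
    eta = rng.normal(0.0, cfg.het_sd, size=m) if cfg.het_sd > 0 else np.zeros(m)
    alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=m)

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_outcome)
    beta_exp = gamma + rng.normal(0.0, 1.0, size=m) * se_exp
    # pleiotropy acts on the exposure-raising allele, so a nonzero mean is
    # directional in the MR-Egger sense (InSIDE-violating)
    true_out = (cfg.beta_causal + eta) * gamma + np.sign(gamma) * alpha
    beta_out = true_out + rng.normal(0.0, 1.0, size=m) * se_out

    snp_ids = [f"rs{cfg.seed % 1000}{j:05d}" for j in range(m)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    pos = 1 + 50_000 * np.arange(m)

    exposure = pd.DataFrame({
        "snp": snp_ids, "chr": "1", "pos": pos, "ea": ea, "oa": oa,
        "eaf": maf, "beta": beta_exp, "se": se_exp,
        "pval": _two_sided_p(beta_exp, se_exp), "n": cfg.n_exposure,
    })

    # a random subset of outcome rows is reported on the opposite allele
    flip = rng.random(m) < 0.3
    out_beta = np.where(flip, -beta_out, beta_out)
    outcome = pd.DataFrame({
        "snp": snp_ids, "chr": "1", "pos": pos,
        "ea": np.where(flip, oa, ea), "oa": np.where(flip, ea, oa),
        "eaf": np.where(flip, 1.0 - maf, maf), "beta": out_beta, "se": se_out,
        "pval": _two_sided_p(beta_out, se_out), "n": cfg.n_outcome,
    })

    ld = np.zeros((m, m))
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        ld[start:stop, start:stop] = cfg.ld_r2
    np.fill_diagonal(ld, 1.0)
    ld_df = pd.DataFrame(ld, index=snp_ids, columns=snp_ids)
    return exposure, outcome, ld_df


@dataclass(frozen=True)
class TraitPanelSpec:
    """Planted-module trait panel: groups of traits with causal links."""

    modules: tuple[tuple[str, ...], ...]
    intra_edge_prob: float = 0.9
    inter_edge_prob: float = 0.05
    effect_size: float = 0.2
    gwas: GwasSimConfig = field(default_factory=GwasSimConfig)
    seed: int = 0

    def validate(self) -> None:
        names = [t for mod in self.modules for t in mod]
        if len(names) != len(set(names)):
            raise ConfigurationError("trait names must be unique across modules")
        if not names:
            raise ConfigurationError("modules must contain at least one trait")
        for p, nm in [(self.intra_edge_prob, "intra_edge_prob"),
                      (self.inter_edge_prob, "inter_edge_prob")]:
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{nm} must be in [0, 1], got {p}")
        if len(self.modules) == 1 and self.inter_edge_prob > 0:
            warnings.warn("single-module spec with inter_edge_prob > 0 has no "
                          "inter-module pairs to draw")


@dataclass
class TraitPanel:
    datasets: dict[tuple[str, str], tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]]
    truth_edges: list[tuple[str, str]]
    module_of: dict[str, int]

    def truth(self) -> dict:
        return {"edges": [list(e) for e in self.truth_edges],
                "modules": dict(self.module_of)}


def simulate_trait_panel(spec: TraitPanelSpec,
                         generate_gwas: bool = True) -> TraitPanel:
    """Draw a planted causal-link panel over the trait groups.

    One GWAS pair per ordered trait pair: planted ("true link",
    beta = effect_size) with probability intra/inter_edge_prob depending on
    module co-membership, else beta = 0.  With ``generate_gwas=False`` only
    the truth is materialized (used by tests that exercise the graph layer).
    """
    spec.validate()
    rng = split_rng(spec.seed, "trait_panel")
    module_of = {t: i + 1 for i, mod in enumerate(spec.modules) for t in mod}
    traits = list(module_of)

    truth_edges: list[tuple[str, str]] = []
    datasets: dict[tuple[str, str], tuple] = {}
    for a, b in itertools.permutations(traits, 2):
        same = module_of[a] == module_of[b]
        p_link = spec.intra_edge_prob if same else spec.inter_edge_prob
        linked = rng.random() < p_link
        if linked:
            truth_edges.append((a, b))
        if generate_gwas:
            pair_seed = int(rng.integers(0, 2**31 - 1))
            cfg = GwasSimConfig(
                **{**spec.gwas.__dict__,
                   "beta_causal": spec.effect_size if linked else 0.0,
                   "seed": pair_seed})
            datasets[(a, b)] = simulate_gwas_pair(cfg)
    return TraitPanel(datasets=datasets, truth_edges=truth_edges, module_of=module_of)


@dataclass(frozen=True)
class ExprSimSpec:
    """Two-group expression matrix with pathway-restricted planted signal."""

    n_cases: int = 50
    n_controls: int = 50
    n_genes: int = 200
    active_sets: tuple[str, ...] = ()
    effect_shift: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigurationError("n_cases and n_controls must each be >= 2")
        if self.effect_shift < 0:
            raise ConfigurationError(f"effect_shift must be >= 0, got {self.effect_shift}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")


def default_gene_names(n_genes: int) -> list[str]:
    return [f"G{j:05d}" for j in range(n_genes)]


def simulate_expression(spec: ExprSimSpec, gene_sets) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Simulate a genes x samples matrix with planted group effects.

    Genes belonging to any set named in ``active_sets`` have their case-group
    mean shifted by ``effect_shift * noise_sd``; all other genes are
    exchangeable between groups.  ``gene_sets`` is a sequence of GeneSet
    records (see :mod:`nexuslipid.enrichment`).
    """
    spec.validate()
    by_name = {s.name: s for s in gene_sets}
    unknown = [n for n in spec.active_sets if n not in by_name]
    if unknown:
        raise ConfigurationError(f"active_sets name(s) not in gene_sets: {unknown}")

    genes = default_gene_names(spec.n_genes)
    universe = set(genes)
    signal_genes = sorted(
        {g for n in spec.active_sets for g in by_name[n].members} & universe)

    rng = split_rng(spec.seed, "expression")
    n = spec.n_cases + spec.n_controls
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    samples = ([f"case{j:03d}" for j in range(spec.n_cases)]
               + [f"ctrl{j:03d}" for j in range(spec.n_controls)])
    labels = pd.Series([1] * spec.n_cases + [0] * spec.n_controls,
                       index=samples, name="label")

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    shift = spec.effect_shift * spec.noise_sd
    matrix.loc[signal_genes, labels[labels == 1].index] += shift

    truth = {"signal_genes": signal_genes, "effect_shift": spec.effect_shift,
             "active_sets": list(spec.active_sets)}
    return matrix, labels, truth


_ACTIONS = ("activation", "inhibition", "binding", "other")


def simulate_chem_edges(n_chemicals: int, n_genes: int,
                        hub_spec: dict[str, int] | None, seed: int,
                        background_max_degree: int = 3,
                        hub_target_pool: list[str] | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Simulate a CTD-style chemical-gene edge table with planted hubs.

    ``hub_spec`` maps planted hub-chemical names to their target-gene degree;
    background chemicals receive degrees in [1, background_max_degree].
    Hub targets are drawn from ``hub_target_pool`` when given (default: the
    whole gene universe).
    """
    hub_spec = dict(hub_spec or {})
    genes = default_gene_names(n_genes)
    pool = sorted(hub_target_pool) if hub_target_pool is not None else genes
    if not set(pool) <= set(genes):
        raise ConfigurationError("hub_target_pool contains genes outside the universe")
    for chem, deg in hub_spec.items():
        if deg > len(pool):
            raise ConfigurationError(
                f"hub {chem!r} requests degree {deg} > pool size {len(pool)}")
        if deg < 1:
            raise ConfigurationError(f"hub {chem!r} degree must be >= 1")

    rng = split_rng(seed, "chem_edges")
    rows = []
    background = [f"chem{j:03d}" for j in range(n_chemicals)]
    chemicals = list(hub_spec) + background
    for i, chem in enumerate(chemicals):
        if chem in hub_spec:
            degree = hub_spec[chem]
            source = pool
        elif n_genes == 0:
            continue
        else:
            degree = int(rng.integers(1, min(background_max_degree, n_genes) + 1))
            source = genes
        targets = rng.choice(source, size=degree, replace=False)
        for g in sorted(targets):
            rows.append({
                "chemical_name": chem,
                "chemical_id": f"MESH:D{i:06d}",
                "gene_symbol": g,
                "action": _ACTIONS[int(rng.integers(0, len(_ACTIONS)))],
            })
    edges = pd.DataFrame(rows, columns=["chemical_name", "chemical_id",
                                        "gene_symbol", "action"])
    truth = {"hubs": hub_spec}
    return edges, truth


def simulate_invivo(n_genes: int, n_per_group: int,
                    deg_spec: dict[str, float] | None, seed: int,
                    baseline_mean: float = 8.0, baseline_sd: float = 1.0,
                    noise_sd: float = 0.5) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Simulate a model-vs-control log2 expression matrix with planted DEGs.

    ``deg_spec`` maps gene names to signed log2 fold changes (model minus
    control).  Truth records each planted gene's linear fold change and
    direction.
    """
    if n_per_group < 2:
        raise ConfigurationError(
            f"n_per_group must be >= 2 (variance undefined), got {n_per_group}")
    deg_spec = dict(deg_spec or {})
    genes = default_gene_names(n_genes)
    universe = set(genes)
    unknown = [g for g in deg_spec if g not in universe]
    if unknown:
        raise ConfigurationError(f"deg_spec gene(s) outside the matrix: {unknown}")

    rng = split_rng(seed, "invivo")
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))
    samples = ([f"model{j}" for j in range(n_per_group)]
               + [f"control{j}" for j in range(n_per_group)])
    groups = pd.Series(["model"] * n_per_group + ["control"] * n_per_group,
                       index=samples, name="group")
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    model_cols = samples[:n_per_group]
    for g, lfc in deg_spec.items():
        matrix.loc[g, model_cols] += lfc

    truth = {
        "planted_degs": {
            g: {"log2fc": lfc, "fold_change": float(2.0 ** lfc),
                "direction": "up" if lfc > 0 else "down"}
            for g, lfc in deg_spec.items()
        }
    }
    return matrix, groups, truth


def make_annotation(n_genes: int, chrom: str = "1", gene_span: int = 20_000,
                    spacing: int = 50_000) -> pd.DataFrame:
    """Tile ``n_genes`` named intervals along one chromosome (BED frame).

    Gene j occupies [j*spacing, j*spacing + gene_span), matching the SNP
    positions emitted by :func:`simulate_gwas_pair` (SNP j at 1-based
    ``1 + j*spacing``), so every simulated instrument maps inside gene j.
    """
    starts = spacing * np.arange(n_genes)
    return pd.DataFrame({
        "chr": chrom,
        "start": starts,
        "end": starts + gene_span,
        "gene": default_gene_names(n_genes),
    })


def make_gene_sets(n_genes: int, n_sets: int, set_size: int, seed: int,
                   domain: str = "BP"):
    """Random overlapping gene sets over the shared synthetic gene universe."""
    from .enrichment import GeneSet

    rng = split_rng(seed, "gene_sets")
    genes = np.array(default_gene_names(n_genes))
    sets = []
    for j in range(n_sets):
        members = rng.choice(genes, size=min(set_size, n_genes), replace=False)
        sets.append(GeneSet(name=f"SET{j:03d}", domain=domain,
                            members=frozenset(members.tolist())))
    return sets
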