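"""Synthetic bulk and single-cell RNA-seq generator with a factorial design.

The generator emulates the structure of a crypt/organoid comparison study:
a full 2 (sample type) × 3 (compartment) × 2 (gender) × 2 (age) factorial
with replicates (96 bulk samples at the defaults), per-factor planted log2
fold-changes on disjoint gene sets, bulk samples formed as cell-type
mixtures over eight intestinal epithelial cell types, and negative-binomial
count sampling with per-gene dispersion and per-sample library size.

The NB parameterization is mean ``mu`` and dispersion ``alpha`` with
``Var = mu + alpha * mu**2``. All randomness flows from one root seed via
named substreams so that any single stage is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CellCounts, CountMatrix, SampleSheet

__all__ = [
    "CELL_TYPES",
    "DEFAULT_FACTOR_LEVELS",
    "EffectSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_design",
    "generate_profiles",
    "plant_effects",
    "simulate_bulk_counts",
    "simulate_sc_counts",
    "simulate_study",
    "substream",
]

DEFAULT_FACTOR_LEVELS: dict = {
    "sample_type": ("crypt", "organoid"),
    "compartment": ("oral", "intermediate", "aboral"),
    "gender": ("male", "female"),
    "age": ("young", "old"),
}

CELL_TYPES = (
    "Stem",
    "TA",
    "LateEnterocyteProgenitor",
    "Enterocyte",
    "Enteroendocrine",
    "Goblet",
    "Paneth",
    "Tuft",
)

# Baseline cell-type proportions: crypt-like tissue is enterocyte-dominated,
# organoid culture favors undifferentiated stem/TA cells.
_CRYPT_PROPS = np.array([0.10, 0.15, 0.12, 0.30, 0.05, 0.15, 0.08, 0.05])
_ORGANOID_PROPS = np.array([0.30, 0.30, 0.08, 0.12, 0.04, 0.08, 0.05, 0.03])


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named RNG substream derived from the root seed."""
    digest = hashlib.blake2b(name.encode(), digest_size=4).digest()
    return np.random.default_rng([int(seed), int.from_bytes(digest, "big")])


@dataclass
class EffectSpec:
    """Planted effect for one factor.

    fraction: share of genes affected by this factor.
    log2fc_mean / log2fc_sd: magnitude distribution of the per-gene |log2FC|
        between the factor's last and first level (intermediate levels are
        placed on a linear gradient).
    shared_in_vitro: probability that an affected gene's effect is also
        present in organoid samples; 1.0 means fully shared, 0.0 means the
        effect exists in vivo only.
    """

    fraction: float = 0.0
    log2fc_mean: float = 2.0
    log2fc_sd: float = 0.5
    shared_in_vitro: float = 1.0


def _default_effects() -> dict:
    # Affected-gene counts allocated roughly proportionally to the default
    # variance targets; magnitudes are rescaled exactly by plant_effects.
    return {
        "sample_type": EffectSpec(fraction=0.12, shared_in_vitro=1.0),
        "compartment": EffectSpec(fraction=0.04, shared_in_vitro=0.8),
        "gender": EffectSpec(fraction=0.026, shared_in_vitro=0.3),
        "age": EffectSpec(fraction=0.014, shared_in_vitro=0.5),
    }


def _default_variance_targets() -> dict:
    return {"sample_type": 0.60, "compartment": 0.20, "gender": 0.13, "age": 0.07}


def _default_compositions() -> dict:
    # Dirichlet concentrations: proportions x precision 200 (low sampling noise).
    return {"crypt": _CRYPT_PROPS * 200.0, "organoid": _ORGANOID_PROPS * 200.0}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults reproduce the study's design."""

    n_genes: int = 2000
    factor_levels: Mapping = field(default_factory=lambda: dict(DEFAULT_FACTOR_LEVELS))
    n_replicates: int = 4
    cell_types: tuple = CELL_TYPES
    effect_spec: Mapping = field(default_factory=_default_effects)
    variance_targets: Mapping | None = field(default_factory=_default_variance_targets)
    dispersion_meanlog: float = math.log(0.05)
    dispersion_sdlog: float = 0.5
    dispersion_floor: float = 1e-4
    library_size: tuple = (300_000.0, 600_000.0)
    composition_spec: Mapping | None = None
    n_markers_per_type: int = 25
    marker_log2_separation: float = 4.0
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    sc_cells_per_type: int = 60
    sc_library_size: tuple = (8_000.0, 12_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        # effect specs for factors not in the design are irrelevant; prune so
        # reduced designs (single factor, toy crossings) keep working
        self.effect_spec = {
            f: s for f, s in self.effect_spec.items() if f in self.factor_levels
        }

    def compositions(self) -> dict:
        """Resolved per-condition Dirichlet concentrations over cell types.

        Defaults: the crypt/organoid presets for the canonical eight cell
        types, otherwise a uniform concentration for every sample_type level.
        """
        if self.composition_spec is not None:
            return dict(self.composition_spec)
        levels = self.factor_levels.get("sample_type", ("crypt",))
        if len(self.cell_types) == len(CELL_TYPES) and tuple(levels) == ("crypt", "organoid"):
            return _default_compositions()
        return {lvl: np.ones(len(self.cell_types)) * 100.0 for lvl in levels}

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for factor, levels in self.factor_levels.items():
            if len(levels) == 0:
                raise ValueError(f"factor {factor!r} has no levels")
            if len(set(levels)) != len(levels):
                raise ValueError(f"factor {factor!r} has duplicate level names")
        for factor, spec in self.effect_spec.items():
            if factor not in self.factor_levels:
                raise ValueError(f"effect_spec names unknown factor {factor!r}")
            if not 0.0 <= spec.fraction <= 1.0:
                raise ValueError(f"effect fraction for {factor!r} outside [0, 1]")
            if not 0.0 <= spec.shared_in_vitro <= 1.0:
                raise ValueError(f"shared_in_vitro for {factor!r} outside [0, 1]")
        if self.variance_targets is not None:
            for factor, share in self.variance_targets.items():
                if not 0.0 <= share <= 1.0:
                    raise ValueError(f"variance target for {factor!r} outside [0, 1]")
        for key, conc in self.compositions().items():
            conc = np.asarray(conc, dtype=float)
            if conc.shape != (len(self.cell_types),):
                raise ValueError(
                    f"composition for {key!r} has {conc.shape[0]} entries, "
                    f"expected {len(self.cell_types)}"
                )
            if (conc <= 0).any():
                raise ValueError(f"composition concentrations for {key!r} must be > 0")
        if self.marker_log2_separation < 3.0:
            raise ValueError("marker_log2_separation must be >= 3 (planted separation)")
        if self.sc_cells_per_type < 10:
            raise ValueError("sc_cells_per_type must be >= 10")

    def null(self) -> "SimulationConfig":
        """Copy of the config with no planted effects and one shared composition."""
        zero = {f: replace(s, fraction=0.0) for f, s in self.effect_spec.items()}
        shared = np.ones(len(self.cell_types)) * 100.0
        conc = {level: shared for level in self.factor_levels.get("sample_type", ())}
        return replace(
            self, effect_spec=zero, variance_targets=None, composition_spec=conc or {"*": shared}
        )


@dataclass
class GroundTruth:
    """Everything needed to score the downstream stages against the truth."""

    true_log2fc: pd.DataFrame  # genes x factors, in-vivo (crypt) effects
    true_log2fc_in_vitro: pd.DataFrame  # genes x factors, effects active in organoids
    true_profiles: pd.DataFrame  # genes x cell types, base mean expression
    affected_gene_sets: dict  # factor -> list of gene IDs
    marker_genes: dict  # cell type -> list of gene IDs
    dispersion: pd.Series  # per-gene NB dispersion alpha
    planted_variance_share: dict  # factor -> realized share of planted log2 variance
    true_compositions: pd.DataFrame | None = None  # samples x cell types (after bulk sim)

    def check(self) -> None:
        zero_rows = ~self.true_log2fc.index.isin(
            [g for gs in self.affected_gene_sets.values() for g in gs]
        )
        if not (self.true_log2fc.loc[zero_rows] == 0).all().all():
            raise AssertionError("unaffected genes must have true_log2fc exactly 0")
        if self.true_compositions is not None:
            sums = self.true_compositions.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise AssertionError("composition rows must sum to 1")


# ---------------------------------------------------------------------------


def generate_design(config: SimulationConfig) -> SampleSheet:
    """Full factorial crossing of all factor levels × replicates.

    Deterministic ordering: factors vary slowest-to-fastest in declared
    order, replicate fastest. Sample IDs encode the levels.
    """
    config.validate()
    factors = list(config.factor_levels)
    rows = []
    combos = [()]
    for factor in factors:
        combos = [c + (lvl,) for c in combos for lvl in config.factor_levels[factor]]
    for combo in combos:
        for rep in range(1, config.n_replicates + 1):
            sample_id = "_".join(combo) + f"_r{rep}"
            rows.append(dict(zip(factors, combo), sample_id=sample_id, replicate=rep))
    frame = pd.DataFrame(rows, columns=["sample_id", *factors, "replicate"])
    return SampleSheet(frame)


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def generate_profiles(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Cell-type reference profiles: shared baseline plus disjoint marker blocks.

    Each cell type owns a disjoint block of ``n_markers_per_type`` genes on
    which its expression is ``2**marker_log2_separation`` times the shared
    baseline, guaranteeing a planted log2 separation >= 3 against every
    other type.

    Returns ``(profiles, marker_genes)`` where profiles is genes × types.
    """
    config.validate()
    if rng is None:
        rng = substream(config.seed, "profiles")
    n_types = len(config.cell_types)
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    n_marker_total = n_types * config.n_markers_per_type
    if n_marker_total >= config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {n_types} marker blocks "
            f"of {config.n_markers_per_type} genes"
        )
    genes = _gene_ids(config.n_genes)
    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, config.n_genes)
    profiles = np.tile(baseline[:, None], (1, n_types))
    marker_genes: dict = {}
    lift = 2.0 ** config.marker_log2_separation
    for k, ctype in enumerate(config.cell_types):
        block = slice(k * config.n_markers_per_type, (k + 1) * config.n_markers_per_type)
        profiles[block, k] *= lift
        marker_genes[ctype] = genes[block]
    return (
        pd.DataFrame(profiles, index=genes, columns=list(config.cell_types)),
        marker_genes,
    )


def _level_weights(n_levels: int) -> np.ndarray:
    """Per-level multipliers of the gene's log2FC: linear 0..1 gradient."""
    if n_levels == 1:
        return np.zeros(1)
    return np.linspace(0.0, 1.0, n_levels)


def plant_effects(config: SimulationConfig, marker_genes: dict, rng=None):
    """Draw per-factor affected gene sets and log2 fold-changes.

    Affected gene sets are disjoint across factors and exclude cell-type
    marker genes (so expression effects and composition effects stay
    separable). If ``variance_targets`` is set, per-factor magnitudes are
    rescaled so the realized shares of planted log2-variance match the
    targets exactly while the total planted variance is preserved.
    """
    config.validate()
    if rng is None:
        rng = substream(config.seed, "effects")
    genes = _gene_ids(config.n_genes)
    reserved = {g for gs in marker_genes.values() for g in gs}
    pool = [g for g in genes if g not in reserved]
    rng.shuffle(pool)
    vivo = pd.DataFrame(0.0, index=genes, columns=list(config.factor_levels))
    vitro = pd.DataFrame(0.0, index=genes, columns=list(config.factor_levels))
    affected: dict = {}
    cursor = 0
    for factor in config.factor_levels:
        spec = config.effect_spec.get(factor, EffectSpec(fraction=0.0))
        n_affected = int(round(spec.fraction * config.n_genes))
        if cursor + n_affected > len(pool):
            raise ValueError("not enough genes to allocate disjoint affected sets")
        chosen = sorted(pool[cursor : cursor + n_affected])
        cursor += n_affected
        affected[factor] = chosen
        if n_affected == 0:
            continue
        magnitude = np.abs(rng.normal(spec.log2fc_mean, spec.log2fc_sd, n_affected))
        magnitude = np.maximum(magnitude, 0.25)
        sign = rng.choice([-1.0, 1.0], n_affected)
        lfc = sign * magnitude
        vivo.loc[chosen, factor] = lfc
        shared = rng.random(n_affected) < spec.shared_in_vitro
        if factor == "sample_type":
            shared[:] = True  # the in vivo/in vitro axis itself is always active
        vitro.loc[chosen, factor] = np.where(shared, lfc, 0.0)

    # Design-variance coefficient per unit log2FC for a balanced factor with
    # levels on a linear gradient: Var(linspace(0, 1, L)).
    coeffs = {
        f: float(np.var(_level_weights(len(lv)))) for f, lv in config.factor_levels.items()
    }
    planted_var = {
        f: coeffs[f] * float((vivo[f] ** 2).sum()) for f in config.factor_levels
    }
    total = sum(planted_var.values())
    if config.variance_targets is not None and total > 0:
        targets = {f: config.variance_targets.get(f, 0.0) for f in config.factor_levels}
        tsum = sum(targets.values())
        if tsum <= 0:
            raise ValueError("variance_targets must have positive total")
        targets = {f: v / tsum for f, v in targets.items()}
        for factor in config.factor_levels:
            if planted_var[factor] > 0:
                scale = math.sqrt(targets[factor] * total / planted_var[factor])
                vivo[factor] *= scale
                vitro[factor] *= scale
        planted_var = {
            f: coeffs[f] * float((vivo[f] ** 2).sum()) for f in config.factor_levels
        }
        total = sum(planted_var.values())
    share = {
        f: (planted_var[f] / total if total > 0 else 0.0) for f in config.factor_levels
    }
    return vivo, vitro, affected, share


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2; Poisson in the alpha→0 limit."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-10
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        n = 1.0 / alpha[nb]
        p = n / (n + mu[nb])
        out[nb] = rng.negative_binomial(n, p)
    return out


def build_truth(config: SimulationConfig) -> GroundTruth:
    """Generate profiles, planted effects and dispersions (no counts yet)."""
    profiles, markers = generate_profiles(config)
    vivo, vitro, affected, share = plant_effects(config, markers)
    rng = substream(config.seed, "dispersion")
    alpha = np.maximum(
        rng.lognormal(config.dispersion_meanlog, config.dispersion_sdlog, config.n_genes),
        config.dispersion_floor,
    )
    return GroundTruth(
        true_log2fc=vivo,
        true_log2fc_in_vitro=vitro,
        true_profiles=profiles,
        affected_gene_sets=affected,
        marker_genes=markers,
        dispersion=pd.Series(alpha, index=profiles.index, name="alpha"),
        planted_variance_share=share,
    )


def simulate_bulk_counts(
    design: SampleSheet, truth: GroundTruth, config: SimulationConfig
) -> CountMatrix:
    """Draw the bulk count matrix for every sample in the design.

    Per sample: expected expression = (Σ_k composition_k × profile_k) ×
    2^(Σ_factors planted log2FC at the sample's levels), scaled to the
    sample's library size; counts ~ NB(mu, alpha). Crypt samples use the
    in-vivo effect matrix, organoid samples the in-vitro one. Realized
    compositions are written back into the ground truth.
    """
    config.validate()
    rng = substream(config.seed, "bulk")
    genes = list(truth.true_profiles.index)
    if len(genes) != config.n_genes:
        raise ValueError("truth and config disagree on the number of genes")
    profiles = truth.true_profiles.to_numpy()
    alpha = truth.dispersion.to_numpy()
    vivo_levels = config.factor_levels["sample_type"]
    in_vivo_level = vivo_levels[0]
    level_mult = {
        f: dict(zip(lv, _level_weights(len(lv)))) for f, lv in config.factor_levels.items()
    }
    compositions = config.compositions()
    comp_rows, count_cols = [], []
    for _, row in design.frame.iterrows():
        key = row.get("sample_type", "*")
        if key not in compositions and "*" not in compositions:
            raise ValueError(f"no composition concentration for condition {key!r}")
        conc = np.asarray(compositions.get(key, compositions.get("*")), dtype=float)
        composition = rng.dirichlet(conc)
        composition = composition / composition.sum()
        comp_rows.append(composition)
        base = profiles @ composition
        effects = (
            truth.true_log2fc if row["sample_type"] == in_vivo_level else truth.true_log2fc_in_vitro
        )
        log2_offset = np.zeros(config.n_genes)
        for factor in config.factor_levels:
            log2_offset += effects[factor].to_numpy() * level_mult[factor][row[factor]]
        mean = base * np.exp2(log2_offset)
        lib = rng.uniform(*config.library_size)
        mu = mean / mean.sum() * lib
        count_cols.append(_nb_draw(rng, mu, alpha))
    truth.true_compositions = pd.DataFrame(
        comp_rows, index=design.sample_ids, columns=list(config.cell_types)
    )
    counts = np.column_stack(count_cols)
    return CountMatrix(genes, design.sample_ids, counts)


def simulate_sc_counts(truth: GroundTruth, config: SimulationConfig):
    """Draw labelled single-cell counts: cells × genes plus a label per cell.

    Each cell's expected expression is proportional to its type's reference
    profile, scaled to a per-cell library size; counts ~ NB(mu, alpha) with
    the gene's bulk dispersion.
    """
    config.validate()
    rng = substream(config.seed, "sc")
    profiles = truth.true_profiles.to_numpy()
    alpha = truth.dispersion.to_numpy()
    cell_ids, labels, rows = [], [], []
    for k, ctype in enumerate(config.cell_types):
        rel = profiles[:, k] / profiles[:, k].sum()
        for i in range(config.sc_cells_per_type):
            lib = rng.uniform(*config.sc_library_size)
            rows.append(_nb_draw(rng, rel * lib, alpha))
            cell_ids.append(f"{ctype}_c{i:04d}")
            labels.append(ctype)
    counts = CellCounts(cell_ids, list(truth.true_profiles.index), np.vstack(rows))
    return counts, labels


def simulate_study(config: SimulationConfig):
    """Run the whole generator: design, truth, bulk counts, single-cell counts.

    Returns ``(design, truth, bulk, cells, labels)``.
    """
    design = generate_design(config)
    truth = build_truth(config)
    bulk = simulate_bulk_counts(design, truth, config)
    cells, labels = simulate_sc_counts(truth, config)
    truth.check()
    return design, truth, bulk, cells, labels
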