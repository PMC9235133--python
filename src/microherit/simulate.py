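"""Synthetic studies with the statistical structure the analysis assumes.

The generator emulates a small commercial rabbit breeding design: a
multi-generation pedigree with half-sib/full-sib structure, full-sib
litters in the final (observed) generation, collective cages holding at
most two littermates each, and the three systematic factors
(farm/diet/regime group, batch, weaning-weight class) at their study
level counts of 6, 5 and 2.  Traits are generated either from the
Gaussian animal model (then put through the x100-and-round count
transformation) or from the zero-inflated Poisson process with the
Gaussian animal model on the log Poisson means, with all true variance
components recorded for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import DesignMatrices, StudyMetadata, TraitTable, build_design, transform_trait
from .pedigree import PedigreeRecord, RelationshipMatrix, build_relationship_matrix, observation_kernel
from .priors import CovarianceKernels, VarianceRatios

logger = logging.getLogger(__name__)

_MAX_COUNT_LOG = float(np.log(1e12))  # overflow guard on the Poisson mean


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the emulated study design."""

    n_founders: int = 128
    n_generations: int = 2
    litter_size: int = 4
    #: litter size of the final (phenotyped) generation; the emulated study
    #: phenotyped ~2 kits per litter, which is what lets cross-litter
    #: pedigree links separate h2 from l2
    observed_litter_size: int | None = 2
    cage_size: int = 8
    max_littermates_per_cage: int = 2
    true_ratios: VarianceRatios = field(
        default_factory=lambda: VarianceRatios(0.25, 0.15, 0.10))
    sigma2_P: float = 1.0
    p_structural: float = 0.0
    beta_scale: float = 0.5  # |beta| <= beta_scale * sigma_P, drawn uniformly
    beta_true: np.ndarray | None = None
    group_levels: int = 6
    batch_levels: int = 5
    weight_levels: int = 2
    trait_kind: str = "genus"
    model: str = "lmm"
    n_traits: int = 1
    zip_baseline: float = float(np.log(30.0))  # exp-scale trait means 10-100
    otu_baseline_sd: float = 5.0  # positive offset for otu-kind Gaussian traits
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2 or self.n_founders % 2:
            raise ValueError("n_founders must be even and >= 2")
        if not 0 <= self.p_structural < 1:
            raise ValueError("p_structural must be in [0, 1)")
        if self.model not in ("lmm", "zip"):
            raise ValueError("model must be 'lmm' or 'zip'")
        if self.max_littermates_per_cage < 1:
            raise ValueError("max_littermates_per_cage must be >= 1")


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus the generating truth."""

    pedigree: list[PedigreeRecord]
    A: RelationshipMatrix
    metadata: StudyMetadata
    design: DesignMatrices
    kernels: CovarianceKernels
    traits: TraitTable
    truth: dict

    @property
    def observed(self) -> list[str]:
        return self.design.animal_ids


def simulate_pedigree(config: SimulationConfig, rng) -> tuple[list[PedigreeRecord], list[list[str]]]:
    """Random-mating pedigree: founders plus ``n_generations`` rounds of
    sire x dam matings, each producing ``litter_size`` offspring.

    Every female of the previous generation produces one litter (so the
    mating count grows with the population) and sires are drawn with
    replacement, giving paternal half-sib families across litters.
    Returns the parent-ordered records and the animal ids per generation;
    sexes alternate within litters so every generation carries both.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    founders = [f"G0_{i:04d}" for i in range(config.n_founders)]
    records = [PedigreeRecord(a, None, None) for a in founders]
    sex = {a: ("M" if i % 2 == 0 else "F") for i, a in enumerate(founders)}
    generations = [founders]

    for g in range(1, config.n_generations + 1):
        parents = generations[g - 1]
        males = [a for a in parents if sex[a] == "M"]
        females = [a for a in parents if sex[a] == "F"]
        if not males or not females:
            raise ValueError("infeasible pedigree: a generation lacks one sex")
        n_matings = len(females)
        sires = rng.choice(males, size=n_matings, replace=True)
        dams = np.array(females)
        size = config.litter_size
        if g == config.n_generations and config.observed_litter_size is not None:
            size = config.observed_litter_size
        gen: list[str] = []
        for m, (s, d) in enumerate(zip(sires, dams)):
            for j in range(size):
                a = f"G{g}_{m:04d}_{j}"
                records.append(PedigreeRecord(a, str(s), str(d)))
                sex[a] = "M" if j % 2 == 0 else "F"
                gen.append(a)
        generations.append(gen)
    return records, generations


def simulate_breeding_values(records, sigma2_a: float, rng,
                             A: RelationshipMatrix | None = None,
                             inbreeding: np.ndarray | None = None) -> np.ndarray:
    """Gene-drop additive values down a sorted pedigree.

    Founders are N(0, sigma2_a); a non-founder gets the parent average plus
    a Mendelian-sampling deviation with variance
    0.5 * sigma2_a * (1 - (F_s + F_d)/2), parental inbreeding F taken from
    the diagonal of A (or supplied directly).  Var(u) = A * sigma2_a by
    construction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if inbreeding is not None:
        F = np.asarray(inbreeding, dtype=float)
        index = {r.animal: i for i, r in enumerate(records)}
    elif all(r.sire is None and r.dam is None for r in records):
        # founders only: independent draws, no relationship matrix needed
        return rng.normal(0.0, np.sqrt(sigma2_a), len(records))
    else:
        if A is None:
            A = build_relationship_matrix(records)
        F = A.inbreeding()
        index = A.index
    u = np.empty(len(records))
    for i, r in enumerate(records):
        si = index.get(r.sire) if r.sire is not None else None
        di = index.get(r.dam) if r.dam is not None else None
        if si is None and di is None:
            u[i] = rng.normal(0.0, np.sqrt(sigma2_a))
            continue
        if si is None or di is None or si >= i or di >= i:
            raise ValueError("gene dropping needs a sorted, two-parent pedigree "
                             "below the founders")
        mend_var = 0.5 * sigma2_a * (1.0 - 0.5 * (F[si] + F[di]))
        u[i] = 0.5 * (u[si] + u[di]) + rng.normal(0.0, np.sqrt(mend_var))
    return u


def assign_litters_cages(records, final_generation, config: SimulationConfig,
                         rng) -> StudyMetadata:
    """Litters are the full-sib groups of the observed generation; cages are
    filled to ``cage_size`` with at most ``max_littermates_per_cage`` animals
    from any one litter per cage.  Batch is assigned per litter; group and
    weight class per animal."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    by_id = {r.animal: r for r in records}
    litter_of: dict[str, str] = {}
    litter_ids: dict[tuple, str] = {}
    for a in final_generation:
        r = by_id[a]
        key = (r.sire, r.dam)
        if key not in litter_ids:
            litter_ids[key] = f"L{len(litter_ids):04d}"
        litter_of[a] = litter_ids[key]

    # greedy cage fill: random eligible cage, opening a new one when needed
    cages: list[dict] = []
    cage_of: dict[str, str] = {}
    order = list(final_generation)
    rng.shuffle(order)
    for a in order:
        lit = litter_of[a]
        eligible = [c for c in cages
                    if c["n"] < config.cage_size
                    and c["litters"].get(lit, 0) < config.max_littermates_per_cage]
        if eligible:
            c = eligible[int(rng.integers(len(eligible)))]
        else:
            c = {"id": f"C{len(cages):04d}", "n": 0, "litters": {}}
            cages.append(c)
        c["n"] += 1
        c["litters"][lit] = c["litters"].get(lit, 0) + 1
        cage_of[a] = c["id"]

    batches = {lid: f"b{int(rng.integers(config.batch_levels))}"
               for lid in litter_ids.values()}
    table = pd.DataFrame(
        {
            "litter": [litter_of[a] for a in final_generation],
            "cage": [cage_of[a] for a in final_generation],
            "batch": [batches[litter_of[a]] for a in final_generation],
            "group": [f"g{int(rng.integers(config.group_levels))}"
                      for _ in final_generation],
            "weight_class": [f"w{int(rng.integers(config.weight_levels))}"
                             for _ in final_generation],
        },
        index=pd.Index(final_generation, name="animal"),
    )
    return StudyMetadata(table)


def _component_effects(study_shape, config: SimulationConfig, rng):
    """Draw (u_obs, litter part, cage part, residual) at the configured
    variance split, each as an observation-level vector."""
    design, records, A, observed = study_shape
    r = config.true_ratios
    s2 = config.sigma2_P
    u_all = simulate_breeding_values(records, r.h2 * s2, rng, A=A)
    idx = [A.index[a] for a in observed]
    u = u_all[idx]
    lit = design.Z_L @ rng.normal(0.0, np.sqrt(r.l2 * s2), design.Z_L.shape[1])
    cag = design.Z_C @ rng.normal(0.0, np.sqrt(r.c2 * s2), design.Z_C.shape[1])
    res = rng.normal(0.0, np.sqrt(r.residual * s2), len(observed))
    return u, lit, cag, res


def simulate_lmm_trait(study_shape, config: SimulationConfig, beta, rng):
    """Gaussian trait under the animal model, then the count transformation."""
    design = study_shape[0]
    u, lit, cag, res = _component_effects(study_shape, config, rng)
    y_raw = design.X @ beta + u + lit + cag + res
    truth = {"u": u, "litter": lit, "cage": cag}
    if config.trait_kind == "otu":
        y_raw = y_raw + config.otu_baseline_sd * np.sqrt(config.sigma2_P)
        neg = y_raw < 0
        if np.any(neg):
            logger.warning("clipping %d negative otu values to 0", int(neg.sum()))
            y_raw = np.where(neg, 0.0, y_raw)
    return transform_trait(y_raw, config.trait_kind), truth


def simulate_zip_trait(study_shape, config: SimulationConfig, beta, rng):
    """Zero-inflated Poisson trait: the animal model generates lambda*, a
    structural zero occurs with probability p, otherwise y ~ Poisson(e^lambda*)."""
    design = study_shape[0]
    u, lit, cag, res = _component_effects(study_shape, config, rng)
    lam_star = config.zip_baseline + design.X @ beta + u + lit + cag + res
    if np.any(lam_star > _MAX_COUNT_LOG):
        logger.warning("clipping %d lambda* values at log(max count)",
                       int(np.sum(lam_star > _MAX_COUNT_LOG)))
        lam_star = np.minimum(lam_star, _MAX_COUNT_LOG)
    y = rng.poisson(np.exp(lam_star))
    structural = rng.uniform(size=y.size) < config.p_structural
    y[structural] = 0
    truth = {"u": u, "litter": lit, "cage": cag, "lambda_star": lam_star,
             "structural_zero": structural}
    return y.astype(np.int64), truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full study: pedigree, metadata, design, kernels and
    ``config.n_traits`` independent traits, deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    records, generations = simulate_pedigree(config, rng)
    observed = generations[-1]
    A = build_relationship_matrix(records)
    metadata = assign_litters_cages(records, observed, config, rng)
    design = build_design(metadata)
    kernels = CovarianceKernels.from_design(observation_kernel(A, observed), design)

    if config.beta_true is not None:
        beta = np.asarray(config.beta_true, dtype=float)
        if beta.size != design.X.shape[1]:
            raise ValueError("beta_true length does not match the design")
    else:
        beta = rng.uniform(-config.beta_scale, config.beta_scale,
                           design.X.shape[1]) * np.sqrt(config.sigma2_P)

    values = {}
    truth_traits = {}
    for t in range(config.n_traits):
        name = f"trait_{t + 1}"
        shape = (design, records, A, observed)
        if config.model == "lmm":
            values[name], tt = simulate_lmm_trait(shape, config, beta, rng)
        else:
            values[name], tt = simulate_zip_trait(shape, config, beta, rng)
        truth_traits[name] = tt

    traits = TraitTable(
        pd.DataFrame(values, index=pd.Index(observed, name="animal")),
        {name: config.trait_kind for name in values},
    )
    truth = {
        "true_ratios": config.true_ratios,
        "sigma2_P": config.sigma2_P,
        "p_structural": config.p_structural,
        "beta_true": beta,
        "per_trait": truth_traits,
    }
    return SimulatedStudy(records, A, metadata, design, kernels, traits, truth)


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write pedigree/metadata/traits in the dialects the readers accept,
    plus a JSON truth file for test harnesses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "metadata": outdir / "metadata.csv",
        "traits": outdir / "traits.csv",
        "truth": outdir / "truth.json",
    }
    ped = pd.DataFrame(
        [(r.animal, r.sire or "0", r.dam or "0") for r in study.pedigree],
        columns=["animal", "sire", "dam"],
    )
    ped.to_csv(paths["pedigree"], index=False)
    study.metadata.table.to_csv(paths["metadata"])
    study.traits.values.to_csv(paths["traits"])
    t = study.truth
    payload = {
        "true_ratios": list(t["true_ratios"].as_array()),
        "sigma2_P": t["sigma2_P"],
        "p_structural": t["p_structural"],
        "beta_true": list(np.asarray(t["beta_true"], dtype=float)),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
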