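"""Per-trait study orchestration.

For every trait passing the >= 5% presence filter the pipeline fits the
linear mixed model, fits the zero-inflated Poisson model when the trait
is non-negative, compares the two by DIC, computes the Savage-Dickey
Bayes factors for the genetic, litter and cage ratios from the chosen
model's chain, and reports posterior summaries, evidence categories and
Geweke diagnostics — one report row per trait, deterministic given the
master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesfactor import chain_bayes_factors
from .datamodel import StudyMetadata, TraitTable, build_design, trait_frequency_class
from .evaluation import dic_from_chain, geweke_z, posterior_summary, select_model
from .lmm import MCMCSettings, run_lmm_mcmc
from .pedigree import build_relationship_matrix, observation_kernel, read_pedigree, sort_pedigree
from .priors import RATIO_NAMES, CovarianceKernels
from .zipmodel import run_zip_mcmc

logger = logging.getLogger(__name__)

REPORT_NAME = "report.tsv"
MANIFEST_NAME = "manifest.json"


@dataclass
class StudyConfig:
    """Paths, sampler settings and output location for a full study run."""

    pedigree: str
    metadata: str
    traits: str
    outdir: str = "microherit_out"
    trait_kinds: dict = field(default_factory=dict)  # trait -> kind, default otu
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    trait_subset: list | None = None
    dump_chains: bool = False

    def __post_init__(self):
        for p in (self.pedigree, self.metadata, self.traits):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        mcmc = MCMCSettings(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)


def _trait_seed(master: int, index: int) -> int:
    return int((master + 1000003 * (index + 1)) % (2**31 - 1))


def analyze_trait(y, design, kernels: CovarianceKernels,
                  settings: MCMCSettings) -> dict:
    """Fit LMM (and ZIP when the trait is non-negative), choose by DIC, and
    assemble the per-trait report entries from the chosen model's chain."""
    y = np.asarray(y)
    row: dict = {}
    lmm_chain = run_lmm_mcmc(y.astype(float), design, kernels, settings)
    dic_lmm = dic_from_chain(lmm_chain, y, design, kernels)
    row["dic_lmm"] = dic_lmm.dic

    if np.any(y < 0):
        row["dic_zip"] = np.nan
        row["zip_skipped"] = "negative integers (standardized trait)"
        chosen, chain = "lmm", lmm_chain
        row["tied"] = False
    else:
        zip_chain = run_zip_mcmc(y, design, kernels, settings)
        dic_zip = dic_from_chain(zip_chain, y, design, kernels)
        row["dic_zip"] = dic_zip.dic
        row["zip_skipped"] = ""
        chosen, tied = select_model(dic_lmm, dic_zip)
        chain = lmm_chain if chosen == "lmm" else zip_chain
        row["tied"] = tied
    row["model"] = chosen

    bfs = chain_bayes_factors(chain)
    for nm in RATIO_NAMES:
        mean, sd, p10 = posterior_summary(chain.ratio(nm), threshold=0.10)
        row[f"{nm}_mean"] = mean
        row[f"{nm}_sd"] = sd
        row[f"{nm}_p_gt_0.10"] = p10
        entry = bfs.get(nm)
        row[f"{nm}_bf"] = entry.bf if entry else np.nan
        row[f"{nm}_evidence"] = entry.evidence if entry else ""
        row[f"{nm}_null_supported"] = entry.null_supported if entry else False
        row[f"{nm}_geweke_z"] = geweke_z(chain.ratio(nm))
    row["_chain"] = chain
    return row


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full per-trait analysis and write the report and manifest."""
    records = sort_pedigree(read_pedigree(config.pedigree))
    metadata = StudyMetadata.read(config.metadata)
    traits = TraitTable.read(config.traits, kinds=config.trait_kinds or None)

    meta_ids, trait_ids = set(metadata.animals), set(traits.animals)
    if meta_ids != trait_ids:
        raise ValueError(
            "metadata/trait animal mismatch: "
            f"only-in-metadata={sorted(meta_ids - trait_ids)[:5]}, "
            f"only-in-traits={sorted(trait_ids - meta_ids)[:5]}")
    ped_ids = {r.animal for r in records}
    missing = meta_ids - ped_ids
    if missing:
        raise ValueError(f"animals absent from pedigree: {sorted(missing)[:5]}")

    metadata.table = metadata.table.loc[traits.animals]
    design = build_design(metadata)
    A = build_relationship_matrix(records)
    kernels = CovarianceKernels.from_design(
        observation_kernel(A, design.animal_ids), design)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [t for t in traits.traits
             if config.trait_subset is None or t in config.trait_subset]
    rows = []
    for idx, name in enumerate(names):
        y = traits.trait(name)
        pct, label, excluded = trait_frequency_class(y)
        row = {"trait": name, "kind": traits.kinds.get(name, "otu"),
               "n": y.size, "freq_pct": round(pct, 4),
               "freq_class": label or "", "excluded": excluded}
        if excluded:
            row["zip_skipped"] = "present in fewer than 5% of animals"
            logger.info("trait %s excluded (%.1f%% nonzero)", name, pct)
        else:
            settings = replace(config.mcmc, seed=_trait_seed(config.mcmc.seed, idx))
            logger.info("fitting trait %s (seed %d)", name, settings.seed)
            row.update(analyze_trait(y, design, kernels, settings))
            chain = row.pop("_chain")
            if config.dump_chains:
                _dump_chain(chain, outdir / f"chain_{name}.tsv")
        rows.append(row)

    report = pd.DataFrame(rows)
    report.to_csv(outdir / REPORT_NAME, sep="\t", index=False, float_format="%.6g")
    manifest = {
        "version": __version__,
        "seed": config.mcmc.seed,
        "n_iter": config.mcmc.n_iter,
        "burnin": config.mcmc.burnin,
        "bf_grid": config.mcmc.bf_grid,
        "bf_stride": config.mcmc.bf_stride,
        "n_animals": len(design.animal_ids),
        "traits": names,
        "trait_seeds": {t: _trait_seed(config.mcmc.seed, i)
                        for i, t in enumerate(names)},
    }
    (outdir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return report


def _dump_chain(chain, path: Path):
    cols = {"deviance": chain.deviance, "sigma2": chain.sigma2}
    for i, nm in enumerate(RATIO_NAMES):
        cols[nm] = chain.ratios[:, i]
    if chain.p_star is not None:
        cols["p_star"] = chain.p_star
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.8g")


def summarize_evidence(report: pd.DataFrame) -> pd.DataFrame:
    """Count traits per (effect x evidence class), plus the null-supported
    tally from the 1/BF rule, over the analyzed (non-excluded) traits."""
    analyzed = report[~report["excluded"]] if "excluded" in report else report
    rows = []
    for nm in RATIO_NAMES:
        counts = {lvl: int((analyzed[f"{nm}_evidence"] == lvl).sum())
                  for lvl in ("none", "substantial", "strong", "decisive")}
        counts["null_supported"] = int(analyzed[f"{nm}_null_supported"].sum())
        rows.append({"effect": nm, **counts})
    return pd.DataFrame(rows).set_index("effect")
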