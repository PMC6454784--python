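"""End-to-end orchestration: generate -> profile -> assemble -> count ->
simulate -> compare.

The full experiment mirrors the five-data-set layout of the study design:

* three *in silico* style pools (database-like, single-copy OTUs; default
  sizes 50, 50 and 35) run through the randomized multiple-of-five design
  with 3000 replicates per group and theoretical (pre-assembly) counting
  with the detection window disabled;
* one *in vitro* style pool (default 72 OTUs, 45 focal-tagged, 20%
  multi-operon) run through the stepwise-nested five-type design, counted
  theoretically under the gel window (pre-assembly) and simulated under
  the amplification-bias model (post-assembly, averaged over a set of
  affinity realizations).

The comparison layer fits the four regression families to each
size-vs-mean-bands curve, runs the unbalanced one-way ANOVA with
Tukey-Kramer contrasts across the five treatments (units = per-group-size
plotted means), screens each treatment with the Lilliefors test, and
builds the theoretical-to-actual fold-loss report.

All randomness derives from one master seed through named sub-streams;
two runs with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import BiasModel, run_bias_scenarios, simulate_post_assembly
from .communities import (
    DEFAULT_CRITERIA,
    MockCommunity,
    RandomizationDesign,
    assemble_nested_mbcs,
    assemble_random_mbcs,
    summarize_groups,
)
from .digestion import GelModel, RestrictionEnzyme, profile_otu
from .io import write_communities_tsv, write_pool_fasta, write_profiles_tsv
from .primers import PRIMER_799F, PRIMER_U1492R
from .stats import (
    REGRESSION_FAMILIES,
    delta_report,
    fit_regression,
    lilliefors,
    tukey_kramer,
    unbalanced_anova,
)
from .synth import PoolSpec, generate_pool

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "derive_seed", "run_theoretical", "run_actual", "run_full"]


def derive_seed(master: int, name: str) -> int:
    """Named 31-bit sub-seed of a master seed (documented derivation:
    SeedSequence(master, spawn_key=(crc32(name),)))."""
    ss = np.random.SeedSequence(master, spawn_key=(zlib.crc32(name.encode()),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class PoolSetting:
    """One pool of the experiment (a named synthetic OTU set)."""

    name: str
    n_otus: int
    multi_operon_fraction: float = 0.0
    focal_fraction: float = 0.0


@dataclass
class RunConfig:
    """Configuration of a full run; round-trips losslessly through YAML."""

    seed: int = 0
    # gel / enzyme
    resolution_bp: int = 5
    window_min_bp: int = 50
    window_max_bp: int = 500
    merge_rule: str = "strict"
    enzyme_site: str = "AGCT"
    enzyme_cut_offset: int = 2
    # randomized (in silico style) arm
    insilico_pools: tuple[PoolSetting, ...] = (
        PoolSetting("reference", 50),
        PoolSetting("rice", 50),
        PoolSetting("bean", 35),
    )
    replicates_per_group: int = 3000
    # nested (in vitro style) arm
    invitro_pool: PoolSetting = field(
        default_factory=lambda: PoolSetting("invitro", 72, 0.2, 45 / 72)
    )
    nested_group_sizes: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    # bias model (post-assembly simulation)
    gamma: float = 1.0
    affinity_distribution: str = "pareto"
    tail_index: float = 0.15
    sigma_bias: float = 1.5
    detect_threshold: float = 0.02
    n_bias_realizations: int = 50
    cp_fractions: tuple[float, ...] = (0.0, 0.35, 0.65, 1.0)
    # comparison layer
    plateau_epsilon: float = 0.2  # bands per 5-OTU step, sizes >= 10
    fold_assertion_band: tuple[float, float] = (2.0, 10.0)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["insilico_pools"] = [asdict(p) for p in self.insilico_pools]
        d["invitro_pool"] = asdict(self.invitro_pool)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "insilico_pools" in d:
            d["insilico_pools"] = tuple(
                PoolSetting(**p) for p in d["insilico_pools"]
            )
        if "invitro_pool" in d:
            d["invitro_pool"] = PoolSetting(**d["invitro_pool"])
        for key in ("nested_group_sizes", "cp_fractions", "fold_assertion_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived objects --------------------------------------------------
    @property
    def gel(self) -> GelModel:
        return GelModel(
            self.resolution_bp, self.window_min_bp, self.window_max_bp, self.merge_rule
        )

    @property
    def enzyme(self) -> RestrictionEnzyme:
        return RestrictionEnzyme("enzyme", self.enzyme_site, self.enzyme_cut_offset)

    def bias_model(self, seed: int) -> BiasModel:
        return BiasModel(
            gamma=self.gamma,
            affinity_distribution=self.affinity_distribution,
            tail_index=self.tail_index,
            sigma_bias=self.sigma_bias,
            detect_threshold=self.detect_threshold,
            seed=seed,
        )


def _make_pool(config: RunConfig, setting: PoolSetting):
    spec = PoolSpec(
        n_otus=setting.n_otus,
        multi_operon_fraction=setting.multi_operon_fraction,
        focal_fraction=setting.focal_fraction,
        resolution_bp=config.resolution_bp,
        seed=derive_seed(config.seed, f"pool:{setting.name}"),
    )
    pool = generate_pool(spec)
    profiles = {
        r.otu_id: profile_otu(r, PRIMER_799F, PRIMER_U1492R, enzyme=config.enzyme)
        for r in pool.records
    }
    return pool, profiles


def _count_all(communities, profiles, gel) -> dict[str, int]:
    """Theoretical band counts for many communities (no provenance kept)."""
    arrays = {o: np.asarray(p.fragments) for o, p in profiles.items()}
    res = gel.resolution_bp
    strict = gel.merge_rule == "strict"
    lo = gel.window_min_bp if gel.window_min_bp is not None else -np.inf
    hi = gel.window_max_bp if gel.window_max_bp is not None else np.inf
    counts: dict[str, int] = {}
    for c in communities:
        frags = np.sort(np.concatenate([arrays[o] for o in c.member_otu_ids]))
        frags = frags[(frags >= lo) & (frags <= hi)]
        n = 0
        anchor = None
        for f in frags:
            d = f - anchor if anchor is not None else None
            if anchor is None or (d >= res if strict else d > res):
                n += 1
                anchor = f
        counts[c.community_id] = n
    return counts


def run_theoretical(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Pre-assembly (theoretical) arm of the experiment.

    Returns a dict with per-set summaries (``insilico`` name -> summary
    frame with the window disabled; ``nested_summary`` under the gel
    window), the per-community nested counts, and the pools/profiles/
    communities needed by the actual arm.
    """
    results: dict = {"insilico": {}, "pools": {}, "profiles": {}}
    for setting in config.insilico_pools:
        pool, profiles = _make_pool(config, setting)
        design = RandomizationDesign.multiples_of_five(
            setting.n_otus,
            replicates_per_group=config.replicates_per_group,
            seed=derive_seed(config.seed, f"random:{setting.name}"),
        )
        communities = assemble_random_mbcs(
            [r.otu_id for r in pool.records], design
        )
        counts = _count_all(communities, profiles, config.gel.windowless())
        results["insilico"][setting.name] = summarize_groups(communities, counts)
        results["pools"][setting.name] = pool
        results["profiles"][setting.name] = profiles

    pool, profiles = _make_pool(config, config.invitro_pool)
    nested = assemble_nested_mbcs(
        pool.taxon_tags,
        DEFAULT_CRITERIA,
        config.nested_group_sizes,
        seed=derive_seed(config.seed, "nested"),
    )
    counts = _count_all(nested, profiles, config.gel)
    results["pools"]["invitro"] = pool
    results["profiles"]["invitro"] = profiles
    results["nested_communities"] = nested
    results["nested_counts"] = pd.DataFrame(
        [
            {
                "community_id": c.community_id,
                "mbc_type": c.mbc_type,
                "group_size": c.group_size,
                "n_bands_theoretical": counts[c.community_id],
            }
            for c in nested
        ]
    )
    results["nested_summary"] = summarize_groups(nested, counts)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results["insilico"].items():
            df.to_csv(out / f"theoretical_insilico_{name}.tsv", sep="\t", index=False)
        results["nested_counts"].to_csv(
            out / "theoretical_nested_counts.tsv", sep="\t", index=False
        )
        results["nested_summary"].to_csv(
            out / "theoretical_nested_summary.tsv", sep="\t", index=False
        )
        write_communities_tsv(nested, out / "nested_communities.tsv")
        write_pool_fasta(pool.records, out / "invitro_pool.fasta")
        write_profiles_tsv(profiles, out / "invitro_profiles.tsv")
    return results


def run_actual(
    config: RunConfig,
    theoretical: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Post-assembly (actual) arm: simulate the nested communities under
    the bias model, averaging band counts over the configured number of
    affinity realizations. Adds the plateau diagnostic (fitted slope of
    mean observed counts over sizes >= 10, in bands per 5-OTU step)."""
    if theoretical is None:
        theoretical = run_theoretical(config)
    profiles = theoretical["profiles"]["invitro"]
    nested: list[MockCommunity] = theoretical["nested_communities"]

    rows = []
    for i in range(config.n_bias_realizations):
        model = config.bias_model(derive_seed(config.seed, f"bias:{i}"))
        for c in nested:
            outcome = simulate_post_assembly(c, profiles, model, config.gel)
            rows.append(
                {
                    "community_id": c.community_id,
                    "mbc_type": c.mbc_type,
                    "group_size": c.group_size,
                    "realization": i,
                    "n_bands_observed": outcome.n_bands,
                }
            )
    obs = pd.DataFrame(rows)
    per_community = (
        obs.groupby(["community_id", "mbc_type", "group_size"])["n_bands_observed"]
        .mean()
        .reset_index()
    )
    summary = (
        obs.groupby("group_size")["n_bands_observed"]
        .agg(n_communities="size", mean_bands="mean", sd_bands="std")
        .reset_index()
    )
    big = summary[summary["group_size"] >= 10]
    slope = float(np.polyfit(big["group_size"], big["mean_bands"], 1)[0] * 5)
    result = {
        "observations": obs,
        "per_community": per_community,
        "actual_summary": summary,
        "plateau_slope_per_5otu": slope,
        "plateau_flag": slope <= config.plateau_epsilon,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_community.to_csv(out / "actual_per_community.tsv", sep="\t", index=False)
        summary.to_csv(out / "actual_summary.tsv", sep="\t", index=False)
    return result


def _treatment_units(theoretical: dict, actual: dict) -> dict[str, list[float]]:
    """The five 'treatments': per-group-size plotted means of each set."""
    units = {
        name: list(df["mean_bands"])
        for name, df in theoretical["insilico"].items()
    }
    units["pre_assembly"] = list(theoretical["nested_summary"]["mean_bands"])
    units["post_assembly"] = list(actual["actual_summary"]["mean_bands"])
    return units


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and assemble the comparison report.

    Returns a dict with the theoretical and actual artifacts plus:
    ``regressions`` (per data set, all four families), ``anova``,
    ``tukey``, ``lilliefors``, ``delta`` (fold-loss report), and the
    competitor-titration ``scenarios`` table on the smallest nested
    type-I communities.
    """
    theoretical = run_theoretical(config, out_dir)
    actual = run_actual(config, theoretical, out_dir)

    regressions: dict[str, dict] = {}
    curves = {
        name: df for name, df in theoretical["insilico"].items()
    }
    curves["pre_assembly"] = theoretical["nested_summary"]
    curves["post_assembly"] = actual["actual_summary"]
    for name, df in curves.items():
        regressions[name] = {}
        for family in REGRESSION_FAMILIES:
            try:
                fit = fit_regression(df["group_size"], df["mean_bands"], family)
            except ValueError:
                continue
            regressions[name][family] = {
                "a": fit.a,
                "b": fit.b,
                "r_squared": fit.r_squared,
                "r_squared_linearized": fit.r_squared_linearized,
                "n": fit.n,
            }

    units = _treatment_units(theoretical, actual)
    labels = list(units)
    anova = unbalanced_anova([units[k] for k in labels])
    tukey = tukey_kramer([units[k] for k in labels], labels=labels)
    lillie = {
        k: dict(
            zip(
                ("d_statistic", "p_value"),
                lilliefors(v, seed=derive_seed(config.seed, f"lilliefors:{k}")),
            )
        )
        for k, v in units.items()
    }

    delta = delta_report(theoretical["nested_summary"], actual["actual_summary"])

    scenarios = run_bias_scenarios(
        [
            c
            for c in theoretical["nested_communities"]
            if c.mbc_type == "I" and c.group_size in (5, 10)
        ],
        theoretical["profiles"]["invitro"],
        config.bias_model(derive_seed(config.seed, "bias:0")),
        config.gel,
        config.cp_fractions,
    )

    report = {
        "version": __version__,
        "seed": config.seed,
        "regressions": regressions,
        "anova": {
            "f_statistic": anova.f_statistic,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p_value": anova.p_value,
            "treatments": labels,
            "group_means": anova.group_means,
            "group_ns": anova.group_ns,
        },
        "tukey": [
            {
                "pair": [p.group_i, p.group_j],
                "mean_difference": p.mean_difference,
                "q_statistic": p.q_statistic,
                "p_value": p.p_value,
                "significant": p.significant,
            }
            for p in tukey.pairs
        ],
        "lilliefors": lillie,
        "delta": {
            "fold_min": delta.fold_min,
            "fold_max": delta.fold_max,
            "undefined_groups": delta.undefined_groups,
            "per_group": delta.table.to_dict(orient="records"),
        },
        "plateau": {
            "slope_per_5otu": actual["plateau_slope_per_5otu"],
            "flag": actual["plateau_flag"],
            "epsilon": config.plateau_epsilon,
        },
    }

    results = {
        **theoretical,
        **actual,
        "regressions": regressions,
        "anova": anova,
        "tukey": tukey,
        "lilliefors": lillie,
        "delta": delta,
        "scenarios": scenarios,
        "report": report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        delta.table.to_csv(out / "delta_per_group.tsv", sep="\t", index=False)
        scenarios.to_csv(out / "competitor_scenarios.tsv", sep="\t", index=False)
        (out / "stats_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        config.to_yaml(out / "run_config.yaml")
        (out / "run_manifest.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "master_seed": config.seed,
                    "derived_seeds": {
                        name: derive_seed(config.seed, name)
                        for name in (
                            ["nested"]
                            + [f"pool:{p.name}" for p in config.insilico_pools]
                            + ["pool:invitro"]
                            + [f"bias:{i}" for i in range(config.n_bias_realizations)]
                        )
                    },
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    return results
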