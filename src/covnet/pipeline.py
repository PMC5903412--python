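"""Config-driven end-to-end covariance network analysis.

Sequences the full analysis on real (TSV) or synthetic inputs:
preprocessing (site regression, outlier exclusion, group covariance) →
distance-decay ANCOVA → network construction over a density sweep → graph
metrics → permutation tests on all group pairs → modular agreement against
constrained nulls.  All randomness derives from one master seed, fanned out
per stage so stages can be re-run in isolation with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distance import centroid_distances, plot_decay, slope_ancova
from .metrics import metrics_table
from .modules import (agreement_difference_test, agreement_test,
                      louvain_partition, symmetric_partition)
from .netbuild import density_sweep
from .perm import permute_groups
from .preprocess import exclude_outliers, group_covariance, regress_site
from .synth import (SynthSpec, make_parcellation, read_cohort_tsv,
                    read_parcellation_tsv, simulate_cohort,
                    write_cohort_tsv, write_parcellation_tsv)

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-stage sub-seed (< 2**31) from the master seed."""
    mix = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; YAML-serialisable."""

    outdir: str = "covnet_out"
    seed: int = 0
    # inputs: either files...
    cohort_tsv: str | None = None
    parcellation_tsv: str | None = None
    # ...or a synthesis spec
    synth: dict | None = None
    # analysis parameters
    densities: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25,
                                    0.30, 0.35, 0.40)
    headline_density: float = 0.10
    hub_fraction: float = 0.10
    permutations: int = 1000
    perm_stats: tuple[str, ...] = ("wiring_cost",)
    fdr_method: str = "BY"
    alpha: float = 0.025
    louvain_restarts: int = 100
    null_ensemble: int = 1000
    density_excludes_mst: bool = False
    rank_by: str = "signed"
    agreement_index: str = "jaccard"
    fisher_z: bool = False
    make_plots: bool = False
    known_sites: tuple[str, ...] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("densities", "perm_stats", "known_sites"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        has_files = self.cohort_tsv is not None and self.parcellation_tsv is not None
        if not has_files and self.synth is None:
            raise ValueError("config needs input TSV paths or a synth spec")
        if has_files:
            for p in (self.cohort_tsv, self.parcellation_tsv):
                if not Path(p).exists():
                    raise FileNotFoundError(p)


_DEFAULT_SYNTH = dict(
    n_per_hemisphere=154,
    n_per_group={"NT": 87, "AUT": 62, "ADHD": 69},
    decay_length={"NT": 110.0, "AUT": 90.0, "ADHD": 70.0},
    sites=("site1", "site2", "site3", "site4"),
    site_offsets={"site1": 0.08, "site2": -0.05, "site3": 0.0,
                  "site4": -0.03},
    planted_modules=None,
    shared_template_groups=(),
    module_boost=0.0,
)


def synthesize_inputs(synth_cfg: dict, seed: int):
    """Build (parcellation, cohort) from a synthesis config dict."""
    cfg = dict(_DEFAULT_SYNTH)
    cfg.update(synth_cfg or {})
    parc = make_parcellation(int(cfg["n_per_hemisphere"]),
                             derive_seed(seed, "parcellation"))
    planted = None
    if cfg.get("planted_modules"):
        m = int(cfg["planted_modules"])
        shared = set(cfg.get("shared_template_groups") or ())
        planted = {}
        shared_template = symmetric_partition(
            parc, m, derive_seed(seed, "planted-shared"))
        for g in cfg["n_per_group"]:
            if not shared or g in shared:
                planted[g] = shared_template.labels
            else:
                planted[g] = symmetric_partition(
                    parc, m, derive_seed(seed, f"planted-{g}")).labels
    spec = SynthSpec(
        n_regions=parc.n_regions,
        n_per_group=dict(cfg["n_per_group"]),
        decay_length={g: float(v) for g, v in cfg["decay_length"].items()},
        sites=tuple(cfg["sites"]),
        site_offsets=dict(cfg["site_offsets"]),
        planted_partition=planted,
        module_boost=float(cfg.get("module_boost") or 0.0),
        rng_seed=derive_seed(seed, "cohort"),
    )
    cohort = simulate_cohort(parc, spec)
    return parc, cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; writes tables/JSON under config.outdir and
    returns the report dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config)}

    # --- inputs
    if config.synth is not None:
        parc, cohort = synthesize_inputs(config.synth, config.seed)
        write_parcellation_tsv(parc, outdir / "parcellation.tsv")
        write_cohort_tsv(cohort, outdir / "cohort.tsv")
    else:
        parc = read_parcellation_tsv(config.parcellation_tsv)
        cohort = read_cohort_tsv(config.cohort_tsv)
    D = centroid_distances(parc)

    # --- preprocess
    known = set(config.known_sites) if config.known_sites else None
    cohort = regress_site(cohort, known_sites=known)
    cohort, excluded = exclude_outliers(cohort)
    (outdir / "exclusions.json").write_text(
        json.dumps({"excluded_subjects": excluded}, indent=2))
    covs = group_covariance(cohort)
    groups = sorted(covs)
    for g, cov in covs.items():
        pd.DataFrame(cov.R).to_csv(outdir / f"covariance_{g}.tsv", sep="\t",
                                   index=False, header=False,
                                   float_format="%.8f")
    report["preprocess"] = {
        "groups": {g: covs[g].n_subjects for g in groups},
        "excluded_subjects": excluded,
        "n_regions": parc.n_regions,
    }

    # --- distance decay
    model = slope_ancova([covs[g] for g in groups], D,
                         fisher_z=config.fisher_z)
    report["distance_decay"] = {
        "F": model.F_stat, "df_num": model.df_num, "df_den": model.df_den,
        "p_overall": model.p_overall,
        "slopes": model.slope, "intercepts": model.intercept,
        "posthoc": {f"{a}-{b}": {"t": t, "p": p}
                    for (a, b), (t, p) in model.posthoc.items()},
    }
    model.summary_frame().to_csv(outdir / "slopes.tsv", sep="\t", index=False,
                                 float_format="%.8g")
    if config.make_plots:
        plot_decay([covs[g] for g in groups], D, model,
                   outdir / "distance_decay.png")

    # --- networks + metrics over the density sweep
    build_kwargs = dict(density_excludes_mst=config.density_excludes_mst,
                        rank_by=config.rank_by)
    nets = {g: density_sweep(covs[g], list(config.densities), **build_kwargs)
            for g in groups}
    metric_frames = []
    for g in groups:
        members = [s for s in cohort if s.group == g]
        for net in nets[g]:
            metric_frames.append(metrics_table(
                g, net.density, net, D, members,
                hub_fraction=config.hub_fraction))
    metrics_df = pd.concat(metric_frames, ignore_index=True)
    metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                      float_format="%.8g")
    headline = {g: _at_density(nets[g], config.headline_density)
                for g in groups}
    report["networks"] = {
        g: {"density": config.headline_density,
            "n_edges": headline[g].n_edges,
            "degree_min": int(headline[g].degrees().min()),
            "degree_max": int(headline[g].degrees().max())}
        for g in groups}

    # --- permutation tests, all group pairs
    perm_rows = []
    for ga, gb in combinations(groups, 2):
        ca = [s for s in cohort if s.group == ga]
        cb = [s for s in cohort if s.group == gb]
        for stat in config.perm_stats:
            test = permute_groups(
                ca, cb, stat, D, B=config.permutations,
                density=config.headline_density,
                rng_seed=derive_seed(config.seed, f"perm-{ga}-{gb}-{stat}"),
                build_kwargs=build_kwargs)
            perm_rows.append({"group_a": ga, "group_b": gb, "statistic": stat,
                              "observed": test.observed, "p": test.p_value,
                              "B": test.n_permutations})
    perm_df = pd.DataFrame(perm_rows)
    perm_df.to_csv(outdir / "permutation_tests.tsv", sep="\t", index=False,
                   float_format="%.8g")
    report["permutation"] = perm_rows

    # --- modular agreement
    partitions = {
        g: louvain_partition(headline[g], n_restarts=config.louvain_restarts,
                             rng_seed=derive_seed(config.seed, f"louvain-{g}"))
        for g in groups}
    pd.DataFrame({"region_id": parc.region_ids,
                  **{f"module_{g}": partitions[g].labels for g in groups}}
                 ).to_csv(outdir / "partitions.tsv", sep="\t", index=False)
    pair_results = []
    for ga, gb in combinations(groups, 2):
        res = agreement_test(
            partitions[ga], partitions[gb], parc, B=config.null_ensemble,
            rng_seed=derive_seed(config.seed, f"agreement-{ga}-{gb}"),
            index=config.agreement_index)
        pair_results.append((f"{ga}-{gb}", res))
    report["modular_agreement"] = {
        name: {"raw": r.raw, "z": r.z, "q95": r.q95, "p": r.p,
               "significant": r.significant,
               "n_modules": [partitions[g].n_modules
                             for g in name.split("-")]}
        for name, r in pair_results}
    if len(pair_results) >= 2:
        diff = agreement_difference_test(pair_results, alpha=config.alpha,
                                         fdr_method=config.fdr_method)
        diff.frame().to_csv(outdir / "agreement_differences.tsv", sep="\t",
                            index=False, float_format="%.8g")
        report["agreement_differences"] = diff.frame().to_dict("records")

    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=_jsonable))
    (outdir / "report.md").write_text(_markdown_report(report))
    return report


def _at_density(nets, density):
    for net in nets:
        if abs(net.density - density) < 1e-12:
            return net
    return nets[0]


def _provenance(config: RunConfig) -> dict:
    cfg = asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {"config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "covnet_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__}


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _markdown_report(report: dict) -> str:
    lines = ["# Structural covariance network analysis report", ""]
    pre = report["preprocess"]
    lines += ["## 1. Cohort and preprocessing",
              f"- regions: {pre['n_regions']}",
              f"- subjects per group: {pre['groups']}",
              f"- excluded subjects: {len(pre['excluded_subjects'])}", ""]
    dd = report["distance_decay"]
    lines += ["## 2. Distance decay of covariance",
              f"- slope-homogeneity F({dd['df_num']}, {dd['df_den']}) = "
              f"{dd['F']:.2f}, p = {dd['p_overall']:.3g}",
              "- slopes (correlation per mm): "
              + ", ".join(f"{g}: {s:.3g}" for g, s in dd["slopes"].items()),
              ""]
    lines += ["## 3. Covariance networks"]
    for g, info in report["networks"].items():
        lines.append(f"- {g}: density {info['density']:.0%}, "
                     f"{info['n_edges']} edges, degree "
                     f"{info['degree_min']}-{info['degree_max']}")
    lines.append("")
    lines += ["## 4. Graph metrics", "- see metrics.tsv (tidy long format)",
              ""]
    lines += ["## 5. Permutation tests"]
    for row in report["permutation"]:
        lines.append(f"- {row['group_a']} vs {row['group_b']} "
                     f"[{row['statistic']}]: observed = "
                     f"{_fmt(row['observed'])}, p = {_fmt(row['p'])} "
                     f"(B = {row['B']})")
    lines.append("")
    lines += ["## 6. Modular agreement"]
    for name, res in report["modular_agreement"].items():
        lines.append(f"- {name}: raw = {res['raw']:.3f}, z = {res['z']:.2f}, "
                     f"95th null quantile = {res['q95']:.3f}, "
                     f"significant = {res['significant']}")
    for row in report.get("agreement_differences", []):
        lines.append(f"- Δ({row['pair_a']} − {row['pair_b']}) = "
                     f"{row['diff']:.3f}, p = {row['p']:.3g}, "
                     f"q = {row['q']:.3g}")
    lines.append("")
    return "\n".join(lines)


def _fmt(x):
    if isinstance(x, (int, float, np.floating)):
        return f"{float(x):.4g}"
    return "vector"
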