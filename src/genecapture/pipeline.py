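"""End-to-end orchestration: filter -> pool -> diversity -> accumulation ->
structure, from one seeded configuration, with a written report bundle.

Every number in the bundle is produced by one public operation of the
library modules; the pipeline only sequences them and serialises results
(delimited tables and JSON) into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accumulation import (
    accumulation_curve,
    allele_membership,
    build_incidence,
    extrapolate_total_richness,
    incidences_per_bunch,
    units_to_threshold,
)
from .diversity import (
    capture_proportion,
    summaries_to_frame,
    summarize_diversity,
    welch_t_test,
)
from .errors import GenecaptureError
from .io import (
    GenotypeDataset,
    Role,
    allele_frequencies,
    filter_missing,
    group_samples,
    pool,
    read_genotype_table,
    write_genotype_table,
)
from .simulate import load_preset, simulate_dataset
from .structure import (
    amova_permutation_test,
    geographic_distance_matrix,
    hierarchical_clustering,
    mantel_test,
    nei_distance_matrix,
)

__all__ = ["PipelineConfig", "load_config", "run_full_analysis"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; ``rng_seed`` is mandatory."""

    rng_seed: int
    input: str | None = None  # genotype table path
    preset: str | None = None  # simulation preset name (alternative to input)
    max_missing: float = 0.25
    rarefaction: int | str = "auto"
    estimator_regional: str = "bootstrap"
    estimator_bunch: str = "chao2"
    n_resamples: int = 999
    n_permutations: int = 999
    thresholds: tuple[float, ...] = (70.0, 90.0)
    out_dir: str | None = None

    def __post_init__(self):
        if self.input is None and self.preset is None:
            raise ValueError("config needs either 'input' or 'preset'")
        if self.input is not None and self.preset is not None:
            raise ValueError("'input' and 'preset' are mutually exclusive")
        for t in self.thresholds:
            if not 0 < t <= 100:
                raise ValueError(f"threshold {t} outside (0, 100]")


_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value config, validating keys and applying defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise GenecaptureError("config file must be a key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise GenecaptureError(f"unknown config key(s): {sorted(unknown)}")
    if "rng_seed" not in raw:
        raise GenecaptureError("config must set rng_seed")
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    return PipelineConfig(**raw)


def dump_config(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["thresholds"] = list(d["thresholds"])
    return d


@dataclass
class ReportBundle:
    """In-memory results of one full run (also serialised when out_dir set)."""

    config: PipelineConfig
    dataset: GenotypeDataset
    filter_report: Any
    regional: pd.DataFrame
    regional_capture_percent: float
    local: pd.DataFrame
    welch: pd.DataFrame
    amova: Any | None
    curves: dict[str, Any] = field(default_factory=dict)
    thresholds: dict[str, dict[float, Any]] = field(default_factory=dict)
    nei: Any | None = None
    newick: str | None = None
    membership: Any | None = None
    mantel: dict[str, Any] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def _curve_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": curve.k,
            "mean": curve.mean,
            "sd": curve.sd,
            "normalized_percent": curve.normalized,
        }
    )


def _threshold_dict(thresholds) -> dict:
    return {
        str(t): {
            "k": res.k,
            "reached": res.reached,
            "extrapolated": res.extrapolated,
        }
        for t, res in thresholds.items()
    }


def run_full_analysis(config: PipelineConfig) -> ReportBundle:
    """Run the complete analysis and (when ``out_dir`` is set) write the
    report bundle; structure stages degrade gracefully (logged in
    ``bundle.skipped``) when the data cannot support them."""
    seeds = np.random.SeedSequence(config.rng_seed).generate_state(8)
    # stage seeds, fixed order: sim, accum_pop, accum_bunch, accum_seeds,
    # amova, mantel_pop, mantel_seed, spare
    if config.preset is not None:
        sim_config = load_preset(config.preset, rng_seed=int(seeds[0] % (2**31)))
        dataset, _truth = simulate_dataset(sim_config)
    else:
        dataset = read_genotype_table(config.input)

    dataset, filt = filter_missing(dataset, config.max_missing)

    # --- regional diversity (pooled populations vs pooled seeds) ----------
    tables = {t.label: t for t in allele_frequencies(dataset, "role")}
    pa_ref = {}
    if "population" in tables and "seed" in tables:
        pa_ref = {"population": "seed", "seed": "population"}
    regional_rows = summarize_diversity(
        dataset, "role", g=config.rarefaction, pa_reference=pa_ref,
        frequency_tables=tables,
    )
    regional = summaries_to_frame(regional_rows)
    by_label = {s.label: s for s in regional_rows}
    capture = float("nan")
    if "population" in by_label and "seed" in by_label:
        capture = capture_proportion(by_label["seed"].ar, by_label["population"].ar)

    # --- local diversity (per population / per bunch) ---------------------
    local_frames = []
    welch_rows = []
    try:
        pops = pool(dataset, Role.POPULATION)
        pop_rows = summarize_diversity(pops, "population", g=config.rarefaction)
        local_frames.append(summaries_to_frame(pop_rows).assign(sample="population"))
    except GenecaptureError:
        pop_rows = []
    try:
        seeds_ds = pool(dataset, Role.SEED)
        bunch_rows = summarize_diversity(seeds_ds, "bunch", g=config.rarefaction)
        local_frames.append(summaries_to_frame(bunch_rows).assign(sample="seeds"))
    except GenecaptureError:
        bunch_rows = []
    local = pd.concat(local_frames, ignore_index=True) if local_frames else pd.DataFrame()

    if len(pop_rows) >= 2 and len(bunch_rows) >= 2:
        for index in ("hprime", "lam", "ho", "hexp", "ar"):
            a = [getattr(r, index) for r in pop_rows]
            b = [getattr(r, index) for r in bunch_rows]
            res = welch_t_test(a, b)
            welch_rows.append(
                {"index": index, "t": res.t, "df": res.df, "p": res.p}
            )
    welch = pd.DataFrame(welch_rows, columns=["index", "t", "df", "p"])

    bundle = ReportBundle(
        config=config,
        dataset=dataset,
        filter_report=filt,
        regional=regional,
        regional_capture_percent=capture,
        local=local,
        welch=welch,
        amova=None,
    )

    # --- AMOVA -------------------------------------------------------------
    pop_samples = [s for s in dataset.samples if s.role is Role.POPULATION]
    pop_names = {s.population for s in pop_samples}
    pop_sizes = [sum(s.population == p for s in pop_samples) for p in pop_names]
    if len(pop_names) >= 2 and min(pop_sizes, default=0) >= 2:
        bundle.amova = amova_permutation_test(
            dataset,
            n_permutations=config.n_permutations,
            rng_seed=int(seeds[4] % (2**31)),
        )
    else:
        bundle.skipped["amova"] = "fewer than 2 populations with >= 2 samples"

    # --- accumulation ------------------------------------------------------
    regional_richness = None
    try:
        inc_pop = build_incidence(dataset, "population")
        regional_richness = extrapolate_total_richness(
            inc_pop, config.estimator_regional
        )
        curve = accumulation_curve(
            inc_pop,
            n_resamples=config.n_resamples,
            rng_seed=int(seeds[1] % (2**31)),
            richness=regional_richness,
            unit_type="population",
        )
        bundle.curves["population"] = curve
        bundle.thresholds["population"] = units_to_threshold(curve, config.thresholds)
    except GenecaptureError as exc:
        bundle.skipped["accumulation_population"] = str(exc)

    try:
        inc_bunch = build_incidence(dataset, "bunch")
        # bunch capture is judged against the extrapolated *regional* total
        richness = regional_richness or extrapolate_total_richness(
            inc_bunch, config.estimator_regional
        )
        curve = accumulation_curve(
            inc_bunch,
            n_resamples=config.n_resamples,
            rng_seed=int(seeds[2] % (2**31)),
            richness=richness,
            unit_type="bunch",
        )
        bundle.curves["bunch"] = curve
        bundle.thresholds["bunch"] = units_to_threshold(curve, config.thresholds)
    except GenecaptureError as exc:
        bundle.skipped["accumulation_bunch"] = str(exc)

    try:
        for i, (bunch, inc_seed) in enumerate(sorted(incidences_per_bunch(dataset).items())):
            richness = extrapolate_total_richness(inc_seed, config.estimator_bunch)
            curve = accumulation_curve(
                inc_seed,
                n_resamples=config.n_resamples,
                rng_seed=int((seeds[3] + i) % (2**31)),
                richness=richness,
                unit_type="seed",
            )
            key = f"seeds:{bunch}"
            bundle.curves[key] = curve
            bundle.thresholds[key] = units_to_threshold(curve, config.thresholds)
    except GenecaptureError as exc:
        bundle.skipped["accumulation_seeds"] = str(exc)

    # --- distances, clustering, membership, Mantel --------------------------
    try:
        group_tables = [
            t
            for t in allele_frequencies(dataset, ["role", "population"])
        ]
        if len(group_tables) >= 2:
            bundle.nei = nei_distance_matrix(group_tables)
            if not bundle.nei.has_infinite:
                bundle.newick = hierarchical_clustering(bundle.nei).to_newick()
            else:
                bundle.skipped["dendrogram"] = "infinite Nei distances present"
    except (GenecaptureError, ValueError) as exc:
        bundle.skipped["nei"] = str(exc)

    try:
        groups = {"populations": pop_samples} if pop_samples else {}
        for bunch, members in group_samples(dataset, "bunch").items():
            if bunch != "None" and any(m.role is Role.SEED for m in members):
                groups[f"bunch:{bunch}"] = [
                    m for m in members if m.role is Role.SEED
                ]
        if len(groups) >= 2:
            bundle.membership = allele_membership(groups, dataset.loci)
    except (GenecaptureError, ValueError) as exc:
        bundle.skipped["membership"] = str(exc)

    for role, label, seed_idx in ((Role.POPULATION, "population", 5),
                                  (Role.SEED, "seed", 6)):
        try:
            members = [s for s in dataset.samples if s.role is role]
            by = "population" if role is Role.POPULATION else "bunch"
            grouped = group_samples(
                dataset.subset([i for i, s in enumerate(dataset.samples)
                                if s.role is role]),
                by,
            )
            coords = {}
            for glabel, gmembers in grouped.items():
                lats = [m.latitude for m in gmembers if m.latitude is not None]
                lons = [m.longitude for m in gmembers if m.longitude is not None]
                if not lats or not lons:
                    raise GenecaptureError("missing coordinates")
                coords[glabel] = (float(np.mean(lats)), float(np.mean(lons)))
            if len(coords) < 3:
                raise GenecaptureError("fewer than 3 groups")
            sub = dataset.subset([i for i, s in enumerate(dataset.samples)
                                  if s.role is role])
            tables_g = allele_frequencies(sub, by)
            gen = nei_distance_matrix(tables_g)
            geo = geographic_distance_matrix(gen.labels, coords)
            bundle.mantel[label] = mantel_test(
                geo, gen,
                n_permutations=config.n_permutations,
                rng_seed=int(seeds[seed_idx] % (2**31)),
            )
        except (GenecaptureError, ValueError) as exc:
            bundle.skipped[f"mantel_{label}"] = str(exc)

    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_table(bundle.dataset, out / "filtered_genotypes.csv")
    bundle.regional.to_csv(out / "regional_diversity.csv", index=False)
    bundle.local.to_csv(out / "local_diversity.csv", index=False)
    bundle.welch.to_csv(out / "welch_tests.csv", index=False)
    for name, curve in bundle.curves.items():
        safe = name.replace(":", "_")
        _curve_frame(curve).to_csv(out / f"accumulation_{safe}.csv", index=False)
    summary: dict[str, Any] = {
        "regional_capture_percent": bundle.regional_capture_percent,
        "filter": {
            "threshold": bundle.filter_report.threshold,
            "dropped_loci": dict(bundle.filter_report.dropped_loci),
            "dropped_samples": dict(bundle.filter_report.dropped_samples),
            "final_missing_percent": bundle.filter_report.final_missing_percent,
        },
        "thresholds": {
            name: _threshold_dict(t) for name, t in bundle.thresholds.items()
        },
        "skipped": bundle.skipped,
    }
    if bundle.amova is not None:
        summary["amova"] = {
            "phi": bundle.amova.phi,
            "percent_within": bundle.amova.percent_within,
            "p_value": bundle.amova.p_value,
            "n_permutations": bundle.amova.n_permutations,
        }
    for label, res in bundle.mantel.items():
        summary[f"mantel_{label}"] = {
            "r": res.r, "p": res.p, "n_permutations": res.n_permutations
        }
    for name, curve in bundle.curves.items():
        summary.setdefault("richness", {})[name] = {
            "s_obs": curve.s_obs,
            "s_hat": curve.richness.s_hat,
            "estimator": curve.richness.estimator,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if bundle.nei is not None:
        bundle.nei.to_frame().to_csv(out / "nei_distances.csv")
    if bundle.newick is not None:
        (out / "dendrogram.nwk").write_text(bundle.newick + "\n")
    if bundle.membership is not None:
        bundle.membership.table.to_csv(out / "allele_membership.csv")
    manifest = {
        "package_version": __version__,
        "config": dump_config(bundle.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
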