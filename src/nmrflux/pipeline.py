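"""Configuration, provenance and end-to-end orchestration.

``run_pipeline`` executes the full chain
simulate -> preprocess -> quantify -> statistics -> flux
on a validated TOML configuration, writing CSV/TSV artifacts plus a
provenance sidecar (``<artifact>.provenance.json``) carrying the tool
version, a config hash stable under key reordering, the random seed and the
stage parameters — enough to re-run any stage exactly.

Stages whose inputs are supplied externally (an ``[inputs]`` section naming a
spectra directory or a concentration table) are skipped.  All randomness
flows from the single ``run.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import fluxmodel, quantify, spectra, stats, synthdata

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; carries the full error list."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


_KNOWN = {
    "run": {"seed", "outdir"},
    "simulate": {
        "cell_lines", "sources", "replicates_per_group", "noise_sd",
        "shift_jitter_sd", "baseline_amp", "biological_cv", "grid_points",
        "base_concentration", "base_concentrations", "effect", "library",
    },
    "preprocess": {
        "region", "exclude_water", "align_intervals", "align_target",
        "max_shift", "normalization", "lb",
    },
    "quantify": {"pls_components"},
    "stats": {
        "anova_by", "anova_threshold", "scaling", "pca_components",
        "corr_diff_line_a", "corr_diff_line_b", "corr_diff_sources", "gmt",
    },
    "flux": {"context"},
    "inputs": {"spectra_dir", "metadata", "concentrations"},
}
_FLUX_CONTEXT_KEYS = {"name", "network", "present_genes", "expr_cutoff", "objective_fraction", "model"}
_EFFECT_KEYS = {"cell_lines", "sources", "metabolites", "factor"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (one section dict per stage)."""

    seed: int
    outdir: str
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    flux_contexts: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config_path() -> Path:
    """Path of the bundled demo configuration."""
    return Path(resources.files("nmrflux") / "data" / "demo_config.toml")


def default_gmt_path() -> Path:
    return Path(resources.files("nmrflux") / "data" / "pathways.gmt")


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    All problems are collected and reported together in a single
    :class:`ConfigError`; unknown keys are rejected.
    """
    data = tomllib.loads(Path(path).read_text())
    errors: list[str] = []

    for section in data:
        if section not in _KNOWN:
            errors.append(f"unknown section [{section}]")
    for section, keys in _KNOWN.items():
        for key in data.get(section, {}):
            if key not in keys:
                errors.append(f"unknown key {key!r} in [{section}]")

    run = data.get("run", {})
    seed = run.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"run.seed must be a non-negative integer, got {seed!r}")
    sim = data.get("simulate", {})
    for key in ("noise_sd", "shift_jitter_sd", "baseline_amp", "biological_cv"):
        if key in sim and sim[key] < 0:
            errors.append(f"simulate.{key} must be >= 0, got {sim[key]}")
    if sim.get("replicates_per_group", 3) < 1:
        errors.append("simulate.replicates_per_group must be >= 1")
    if sim.get("grid_points", synthdata.DEFAULT_GRID_POINTS) < 16:
        errors.append("simulate.grid_points must be >= 16")
    for eff in sim.get("effect", []):
        for key in eff:
            if key not in _EFFECT_KEYS:
                errors.append(f"unknown key {key!r} in [[simulate.effect]]")
        if eff.get("factor", 1.0) <= 0:
            errors.append(f"effect factor must be > 0, got {eff.get('factor')}")
    if "library" in sim and not Path(sim["library"]).exists():
        errors.append(f"simulate.library path does not exist: {sim['library']}")

    flux_contexts = data.get("flux", {}).get("context", [])
    for ctx in flux_contexts:
        for key in ctx:
            if key not in _FLUX_CONTEXT_KEYS:
                errors.append(f"unknown key {key!r} in [[flux.context]]")
        net = ctx.get("network")
        if net not in synthdata.TOY_NETWORK_KINDS and "model" not in ctx:
            errors.append(f"flux context {ctx.get('name')!r}: unknown network {net!r}")
        frac = ctx.get("objective_fraction", fluxmodel.DEFAULT_OBJECTIVE_FRACTION)
        if not 0 < frac <= 1:
            errors.append(f"flux context {ctx.get('name')!r}: objective_fraction {frac} not in (0, 1]")

    inputs = data.get("inputs", {})
    for key, val in inputs.items():
        if not Path(val).exists():
            errors.append(f"inputs.{key} path does not exist: {val}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        seed=seed,
        outdir=run.get("outdir", "nmrflux_out"),
        simulate=sim,
        preprocess=data.get("preprocess", {}),
        quantify=data.get("quantify", {}),
        stats=data.get("stats", {}),
        flux_contexts=flux_contexts,
        inputs=inputs,
    )


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def _provenance(config: RunConfig, stage: str, params: dict) -> dict:
    return {
        "tool": "nmrflux",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage": stage,
        "params": params,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _write_artifact(df: pd.DataFrame, path: Path, config: RunConfig, stage: str, params: dict) -> Path:
    df.to_csv(path, float_format="%.10g")
    Path(f"{path}.provenance.json").write_text(
        json.dumps(_provenance(config, stage, params), indent=1, default=str)
    )
    return path


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def build_cohort_design(config: RunConfig) -> tuple[synthdata.CohortDesign, list[synthdata.MetaboliteDef]]:
    sim = config.simulate
    if "library" in sim:
        defs = synthdata.load_library_definitions(sim["library"])
    else:
        defs = synthdata.default_library_definitions()
    names = [m.name for m in defs]
    base_default = float(sim.get("base_concentration", 1.0))
    base = {n: base_default for n in names}
    base.update(sim.get("base_concentrations", {}))
    groups = [
        (line, src)
        for line in sim.get("cell_lines", ["LN18", "A172", "U118", "NHA"])
        for src in sim.get("sources", ["cell", "EV", "media"])
    ]
    effects: dict = {}
    for eff in sim.get("effect", []):
        for line in eff.get("cell_lines", []):
            for src in eff.get("sources", []):
                for met in eff.get("metabolites", []):
                    effects[((line, src), met)] = float(eff["factor"])
    design = synthdata.CohortDesign(
        groups=groups,
        replicates_per_group=int(sim.get("replicates_per_group", 3)),
        base_concentrations=base,
        effects=effects,
        noise_sd=float(sim.get("noise_sd", 0.0)),
        shift_jitter_sd=float(sim.get("shift_jitter_sd", 0.0)),
        baseline_amp=float(sim.get("baseline_amp", 0.0)),
        biological_cv=float(sim.get("biological_cv", synthdata.DEFAULT_BIOLOGICAL_CV)),
        seed=config.seed,
    )
    return design, defs


def preprocess_spectra(spectra_list, config: RunConfig):
    """Trim, water-exclude and co-shift a spectrum set per the config."""
    pp = config.preprocess
    out = list(spectra_list)
    if "region" in pp:
        out = [spectra.trim_region(s, pp["region"]) for s in out]
    if pp.get("exclude_water"):
        out = [spectra.exclude_region(s, pp["exclude_water"]) for s in out]
    norm = pp.get("normalization")
    if norm == "ref":
        out = [spectra.normalize_reference_peak(s) for s in out]
    elif norm == "total":
        out = [spectra.normalize_total_area(s) for s in out]
    elif norm not in (None, "none"):
        raise ConfigError([f"unknown normalization {norm!r}"])
    intervals = pp.get("align_intervals", [])
    if intervals and len(out) > 1:
        out, _ = spectra.align_icoshift(
            out,
            intervals,
            target=pp.get("align_target", "median"),
            max_shift=int(pp.get("max_shift", spectra.DEFAULT_MAX_SHIFT)),
        )
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict[str, Path]:
    """Execute the configured stage chain; returns artifact name -> path."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    logger.info("run seed=%d outdir=%s config=%s", config.seed, outdir, config.config_hash())

    design, defs = build_cohort_design(config)
    grid = synthdata.default_grid(int(config.simulate.get("grid_points", synthdata.DEFAULT_GRID_POINTS)))
    library = quantify.SpectralLibrary.from_definitions(defs, grid)

    # --- simulate (skipped when spectra are supplied externally) ----------
    if "spectra_dir" in config.inputs:
        meta = pd.read_csv(config.inputs["metadata"], index_col=0)
        cohort = []
        for sid, rec in meta.iterrows():
            s = spectra.read_spectrum_tsv(
                Path(config.inputs["spectra_dir"]) / f"{sid}.tsv",
                meta={"sample_id": sid, **rec.to_dict()},
            )
            cohort.append(s)
        metadata = meta
    else:
        cohort, truth = synthdata.make_cohort(design, defs, grid)
        paths = synthdata.write_cohort(cohort, truth, outdir)
        params = {"design": str(design)}
        for key, p in paths.items():
            artifacts[key] = p
        Path(f"{paths['ground_truth']}.provenance.json").write_text(
            json.dumps(_provenance(config, "simulate", params), indent=1, default=str)
        )
        metadata = pd.DataFrame(
            [
                {
                    "sample_id": s.meta["sample_id"],
                    "cell_line": s.meta["cell_line"],
                    "source": s.meta["source"],
                    "replicate": s.meta["replicate"],
                }
                for s in cohort
            ]
        ).set_index("sample_id")

    # --- preprocess + quantify -------------------------------------------
    if "concentrations" in config.inputs:
        table = pd.read_csv(config.inputs["concentrations"], index_col=0)
    else:
        processed = preprocess_spectra(cohort, config)
        table = quantify.quantify_cohort(
            library, processed, n_components=config.quantify.get("pls_components")
        )
        artifacts["concentrations"] = _write_artifact(
            table, outdir / "concentrations.csv", config, "quantify",
            {"pls_components": config.quantify.get("pls_components"), **config.preprocess},
        )

    # --- statistics --------------------------------------------------------
    st = config.stats
    by = st.get("anova_by", "source")
    labels = metadata[by]
    threshold = float(st.get("anova_threshold", stats.DEFAULT_ANOVA_THRESHOLD))
    ranking = stats.anova_rank(table, labels, threshold=threshold)
    artifacts["anova_ranking"] = _write_artifact(
        ranking.set_index("metabolite"), outdir / "anova_ranking.csv", config,
        "stats", {"anova_by": by, "threshold": threshold},
    )

    scaled = stats.zscale(table, mode=st.get("scaling", "per_metabolite"))
    n_comp = int(st.get("pca_components", 2))
    scores, loadings, explained = stats.pca(scaled.to_numpy(), n_comp)
    artifacts["pca_scores"] = _write_artifact(
        pd.DataFrame(scores, index=table.index, columns=[f"PC{i+1}" for i in range(n_comp)]),
        outdir / "pca_scores.csv", config, "stats", {"components": n_comp},
    )
    artifacts["pca_loadings"] = _write_artifact(
        pd.DataFrame(loadings, index=table.columns, columns=[f"PC{i+1}" for i in range(n_comp)]),
        outdir / "pca_loadings.csv", config, "stats", {"components": n_comp},
    )
    artifacts["pca_explained"] = _write_artifact(
        pd.DataFrame({"explained_variance_fraction": explained},
                     index=pd.Index([f"PC{i+1}" for i in range(n_comp)], name="component")),
        outdir / "pca_explained.csv", config, "stats", {"components": n_comp},
    )

    line_a = st.get("corr_diff_line_a")
    line_b = st.get("corr_diff_line_b")
    if line_a and line_b:
        srcs = st.get("corr_diff_sources", ["EV", "media"])
        sel_a = metadata.index[(metadata["cell_line"] == line_a) & metadata["source"].isin(srcs)]
        sel_b = metadata.index[(metadata["cell_line"] == line_b) & metadata["source"].isin(srcs)]
        delta = stats.correlation_difference(table.loc[sel_a], table.loc[sel_b])
        artifacts["corr_diff"] = _write_artifact(
            delta, outdir / "corr_diff.csv", config, "stats",
            {"line_a": line_a, "line_b": line_b, "sources": srcs},
        )

    gmt_path = st.get("gmt", default_gmt_path())
    pathways = stats.read_gmt(gmt_path)
    universe = set(table.columns)
    selected = set(ranking.loc[ranking["selected"], "metabolite"]) & universe
    if selected:
        ora = stats.ora_hypergeometric(selected, pathways, universe)
        artifacts["ora"] = _write_artifact(
            ora.set_index("pathway"), outdir / "ora.csv", config, "stats",
            {"gmt": str(gmt_path), "n_selected": len(selected)},
        )

    # --- flux simulation ---------------------------------------------------
    summary_rows = []
    for ctx in config.flux_contexts:
        if "model" in ctx:
            model = fluxmodel.read_model(ctx["model"])
        else:
            model = synthdata.make_toy_network(ctx["network"])
        profile = synthdata.make_expression_profile(model, set(ctx.get("present_genes", [])))
        rxn_expr = fluxmodel.reaction_expression(model, profile)
        cutoff = float(ctx.get("expr_cutoff", fluxmodel.DEFAULT_EXPR_CUTOFF))
        fraction = float(ctx.get("objective_fraction", fluxmodel.DEFAULT_OBJECTIVE_FRACTION))
        sol = fluxmodel.gimme(model, rxn_expr, expr_cutoff=cutoff, objective_fraction=fraction)
        tag = f"{ctx['name']}_{ctx.get('network', 'model')}"
        flux_path = outdir / f"fluxes_{tag}.csv"
        fluxmodel.write_flux_csv(sol, flux_path, rxn_expr, cutoff)
        Path(f"{flux_path}.provenance.json").write_text(
            json.dumps(_provenance(config, "flux", {
                "context": ctx["name"], "network": ctx.get("network"),
                "expr_cutoff": cutoff, "objective_fraction": fraction,
            }), indent=1, default=str)
        )
        artifacts[f"fluxes_{tag}"] = flux_path
        sub, dead = fluxmodel.context_subnetwork(model, sol)
        fluxmodel.write_model(sub, outdir / f"subnetwork_{tag}.json", format="json")
        artifacts[f"subnetwork_{tag}"] = outdir / f"subnetwork_{tag}.json"
        summary_rows.append(
            {
                "context": ctx["name"],
                "network": ctx.get("network", "model"),
                "status": sol.status,
                "objective_value": sol.objective_value,
                "inconsistency_score": sol.inconsistency_score,
                "active_reactions": len(sub.reactions),
                "dead_end_metabolites": ";".join(dead),
            }
        )
    if summary_rows:
        artifacts["flux_summary"] = _write_artifact(
            pd.DataFrame(summary_rows).set_index(["context", "network"]),
            outdir / "flux_summary.csv", config, "flux", {},
        )
    return artifacts
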