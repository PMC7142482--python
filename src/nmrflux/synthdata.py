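"""Synthetic inputs for the whole pipeline.

Generates everything the downstream stages need without external downloads:

* pure-metabolite reference spectra as sums of Lorentzian lines normalized to
  unit total (summed) intensity — synthetic stand-ins for database standard
  spectra;
* mixture spectra with known non-negative concentrations plus Gaussian noise,
  per-metabolite chemical-shift jitter and low-order polynomial baseline
  drift;
* cohorts mirroring a cell-line x sample-source design (glioblastoma lines
  LN18/A172/U118 and normal astrocytes NHA; cell / EV / media sources) with
  planted multiplicative group effects and lognormal biological variation;
* small stoichiometric toy networks (chain, branched alternatives, mini TCA
  fragment, glutathione-like branch) with gene-protein-reaction rules;
* boolean protein-presence profiles (present = 100, absent = 0).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fluxmodel import MetabolicModel
from .spectra import Spectrum, write_spectrum_tsv

DEFAULT_GRID_POINTS = 32768
DEFAULT_GRID_RANGE = (-0.5, 10.0)
DEFAULT_BIOLOGICAL_CV = 0.1


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian line: center (ppm), relative amplitude, FWHM (ppm)."""

    center: float
    amplitude: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise SynthesisError(f"amplitude must be > 0, got {self.amplitude}")
        if self.fwhm <= 0:
            raise SynthesisError(f"fwhm must be > 0, got {self.fwhm}")


@dataclass(frozen=True)
class MetaboliteDef:
    """Named metabolite with at least one Lorentzian peak."""

    name: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise SynthesisError(f"metabolite {self.name!r} has no peaks")
        object.__setattr__(self, "peaks", tuple(self.peaks))


@dataclass
class CohortDesign:
    """Cohort layout with planted group-level multiplicative effects.

    ``groups`` are (cell_line, source) labels; ``effects`` maps
    ((cell_line, source), metabolite) to a multiplicative factor > 0 applied
    to that group's mean.  Replicate concentrations are drawn as
    base * effect * lognormal(0, biological_cv).
    """

    groups: list[tuple[str, str]]
    replicates_per_group: int
    base_concentrations: dict[str, float]
    effects: dict[tuple[tuple[str, str], str], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    shift_jitter_sd: float = 0.0
    baseline_amp: float = 0.0
    biological_cv: float = DEFAULT_BIOLOGICAL_CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_group < 1:
            raise SynthesisError("replicates_per_group must be >= 1")
        for k, v in self.base_concentrations.items():
            if v < 0:
                raise SynthesisError(f"base concentration for {k!r} is negative")
        for k, f in self.effects.items():
            if f <= 0:
                raise SynthesisError(f"effect factor for {k!r} must be > 0")
        for p in (self.noise_sd, self.shift_jitter_sd, self.baseline_amp, self.biological_cv):
            if p < 0:
                raise SynthesisError("noise/jitter/baseline/CV parameters must be >= 0")


def default_grid(
    n_points: int = DEFAULT_GRID_POINTS, span: Sequence[float] = DEFAULT_GRID_RANGE
) -> np.ndarray:
    """The default acquisition grid: ``n_points`` over -0.5 to 10 ppm."""
    return np.linspace(span[0], span[1], n_points)


def lorentzian(x: np.ndarray, center: float, amplitude: float, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return amplitude * hw**2 / ((x - center) ** 2 + hw**2)


def _raw_profile(met: MetaboliteDef, grid: np.ndarray, shift: float = 0.0) -> np.ndarray:
    y = np.zeros_like(grid)
    for p in met.peaks:
        y += lorentzian(grid, p.center + shift, p.amplitude, p.fwhm)
    return y


def make_reference_spectrum(met: MetaboliteDef, grid: np.ndarray) -> Spectrum:
    """Unit-total-intensity standard spectrum of a pure metabolite.

    The Lorentzian sum is rescaled so the summed intensity over the grid is
    exactly 1, the convention used for library standards.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise SynthesisError("grid must be a strictly increasing 1-D axis")
    y = _raw_profile(met, grid)
    total = y.sum()
    if total <= 0:
        raise SynthesisError(f"metabolite {met.name!r} has no intensity on the grid")
    return Spectrum(
        grid,
        y / total,
        {"metabolite": met.name},
        [{"op": "make_reference_spectrum", "metabolite": met.name}],
    )


def make_mixture(
    library_defs: Sequence[MetaboliteDef],
    concentrations: Sequence[float],
    grid: np.ndarray,
    noise_sd: float = 0.0,
    shift_jitter_sd: float = 0.0,
    baseline_amp: float = 0.0,
    seed: int | np.random.Generator = 0,
    per_peak_jitter: bool = False,
) -> tuple[Spectrum, np.ndarray]:
    """Mixture spectrum with known ground truth.

    spectrum = sum_i c_i * (reference_i rigidly shifted by ppm jitter)
               + low-order polynomial baseline + Gaussian noise

    Jitter emulates pH-driven shift variation and is rigid per metabolite by
    default (``per_peak_jitter=True`` jitters each line independently).  The
    ground-truth concentration vector is returned verbatim.
    """
    grid = np.asarray(grid, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if conc.size != len(library_defs):
        raise SynthesisError(
            f"{conc.size} concentrations for {len(library_defs)} metabolites"
        )
    if np.any(conc < 0):
        raise SynthesisError("concentrations must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    y = np.zeros_like(grid)
    for met, c in zip(library_defs, conc):
        if per_peak_jitter and shift_jitter_sd > 0:
            shifted = MetaboliteDef(
                met.name,
                tuple(
                    PeakSpec(p.center + rng.normal(0, shift_jitter_sd), p.amplitude, p.fwhm)
                    for p in met.peaks
                ),
            )
            ref = make_reference_spectrum(shifted, grid).intensity
        else:
            shift = rng.normal(0, shift_jitter_sd) if shift_jitter_sd > 0 else 0.0
            raw = _raw_profile(met, grid, shift=shift)
            total = raw.sum()
            ref = raw / total if total > 0 else raw
        y += c * ref

    if baseline_amp > 0:
        # degree-3 polynomial drift, scaled to peak |baseline_amp|
        x = np.linspace(-1, 1, grid.size)
        coeffs = rng.normal(0, 1, size=4)
        base = np.polyval(coeffs, x)
        peak = np.abs(base).max()
        if peak > 0:
            y += baseline_amp * base / peak
    if noise_sd > 0:
        y += rng.normal(0, noise_sd, size=grid.size)

    spec = Spectrum(
        grid,
        y,
        {},
        [
            {
                "op": "make_mixture",
                "noise_sd": noise_sd,
                "shift_jitter_sd": shift_jitter_sd,
                "baseline_amp": baseline_amp,
            }
        ],
    )
    return spec, conc.copy()


def make_cohort(
    design: CohortDesign,
    library_defs: Sequence[MetaboliteDef],
    grid: np.ndarray | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate a replicated cohort with planted group effects.

    Returns the spectra (metadata: sample_id, cell_line, source, replicate)
    and the ground-truth concentration table (samples x metabolites).
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    names = [m.name for m in library_defs]
    unknown = {met for (_, met) in design.effects} - set(names)
    if unknown:
        raise SynthesisError(f"effects reference unknown metabolites {sorted(unknown)}")
    base = np.array([design.base_concentrations.get(n, 0.0) for n in names])
    rng = np.random.default_rng(design.seed)

    spectra: list[Spectrum] = []
    rows, ids = [], []
    for group in design.groups:
        line, source = group
        factors = np.array(
            [design.effects.get((tuple(group), n), 1.0) for n in names]
        )
        for rep in range(1, design.replicates_per_group + 1):
            if design.biological_cv > 0:
                bio = rng.lognormal(mean=0.0, sigma=design.biological_cv, size=len(names))
            else:
                bio = np.ones(len(names))
            conc = base * factors * bio
            spec, truth = make_mixture(
                library_defs,
                conc,
                grid,
                noise_sd=design.noise_sd,
                shift_jitter_sd=design.shift_jitter_sd,
                baseline_amp=design.baseline_amp,
                seed=rng,
            )
            sample_id = f"{line}_{source}_r{rep}"
            spec.meta.update(
                sample_id=sample_id, cell_line=line, source=source, replicate=rep
            )
            spectra.append(spec)
            ids.append(sample_id)
            rows.append(truth)
    truth_table = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=names)
    return spectra, truth_table


# ---------------------------------------------------------------------------
# built-in metabolite panel
# ---------------------------------------------------------------------------
# Synthetic stand-ins for database standard spectra: names and approximate
# chemical shifts follow the usual 1H assignments of a 20-metabolite panel
# typical of cell/EV/media extracts; amplitudes loosely track proton counts.

_PANEL: list[tuple[str, list[tuple[float, float, float]]]] = [
    ("lactate", [(1.33, 3.0, 0.02), (4.11, 1.0, 0.02)]),
    ("alanine", [(1.48, 3.0, 0.02), (3.78, 1.0, 0.02)]),
    ("5-oxoproline", [(2.03, 2.0, 0.025), (2.40, 1.5, 0.025), (4.18, 1.0, 0.02)]),
    ("glutamine", [(2.14, 2.0, 0.025), (2.45, 2.0, 0.025), (3.77, 1.0, 0.02)]),
    ("tryptophan", [(7.28, 1.0, 0.02), (7.54, 1.0, 0.02), (7.73, 1.0, 0.02), (4.05, 1.0, 0.02)]),
    ("succinate", [(2.41, 4.0, 0.018)]),
    ("citrate", [(2.54, 2.0, 0.02), (2.66, 2.0, 0.02)]),
    ("malate", [(2.37, 1.0, 0.022), (2.68, 1.0, 0.022), (4.30, 1.0, 0.02)]),
    ("creatine", [(3.03, 3.0, 0.016), (3.93, 2.0, 0.018)]),
    ("carnitine", [(3.22, 9.0, 0.018), (2.44, 2.0, 0.022), (4.57, 1.0, 0.02)]),
    ("choline", [(3.19, 9.0, 0.016), (3.51, 2.0, 0.02), (4.06, 2.0, 0.02)]),
    ("glycine", [(3.55, 2.0, 0.015)]),
    ("glycerol", [(3.56, 2.0, 0.022), (3.65, 2.0, 0.022), (3.78, 1.0, 0.02)]),
    ("threonine", [(1.32, 3.0, 0.02), (3.58, 1.0, 0.02), (4.25, 1.0, 0.02)]),
    ("homoserine", [(1.90, 1.0, 0.025), (2.10, 1.0, 0.025), (3.85, 1.0, 0.02)]),
    ("myo-inositol", [(3.27, 1.0, 0.02), (3.52, 2.0, 0.02), (3.61, 2.0, 0.02), (4.06, 1.0, 0.02)]),
    ("glucose", [(3.40, 2.0, 0.025), (3.72, 2.0, 0.025), (5.22, 1.0, 0.018)]),
    ("methionine", [(2.13, 3.0, 0.018), (2.64, 2.0, 0.02), (3.86, 1.0, 0.02)]),
    ("gsh", [(2.16, 2.0, 0.025), (2.55, 2.0, 0.025), (2.95, 2.0, 0.022), (3.77, 2.0, 0.022)]),
    ("gssg", [(2.18, 2.0, 0.025), (2.98, 2.0, 0.022), (3.30, 2.0, 0.022), (4.75, 1.0, 0.02)]),
]


def default_library_definitions() -> list[MetaboliteDef]:
    """The built-in 20-metabolite synthetic panel."""
    return [
        MetaboliteDef(name, tuple(PeakSpec(c, a, w) for c, a, w in peaks))
        for name, peaks in _PANEL
    ]


def load_library_definitions(path: str | Path) -> list[MetaboliteDef]:
    """Metabolite/peak definitions from a TOML file.

    Format::

        [[metabolite]]
        name = "lactate"
        peaks = [[1.33, 3.0, 0.02], [4.11, 1.0, 0.02]]   # center, amplitude, fwhm
    """
    data = tomllib.loads(Path(path).read_text())
    defs = []
    names = set()
    for entry in data.get("metabolite", []):
        name = entry["name"]
        if name in names:
            raise SynthesisError(f"duplicate metabolite name {name!r}")
        names.add(name)
        defs.append(
            MetaboliteDef(name, tuple(PeakSpec(*p) for p in entry["peaks"]))
        )
    if not defs:
        raise SynthesisError(f"{path}: no [[metabolite]] entries")
    return defs


# ---------------------------------------------------------------------------
# toy stoichiometric networks
# ---------------------------------------------------------------------------

def _model(mets, rxn_rows, objective):
    """rxn_rows: (id, {met: coeff}, lb, ub, gpr)."""
    rids = [r[0] for r in rxn_rows]
    S = np.zeros((len(mets), len(rids)))
    midx = {m: i for i, m in enumerate(mets)}
    genes = set()
    for j, (_, coeffs, _, _, gpr) in enumerate(rxn_rows):
        for m, c in coeffs.items():
            S[midx[m], j] = c
        genes |= {g for g in gpr.replace("(", " ").replace(")", " ").split() if g.lower() not in ("and", "or")}
    return MetabolicModel(
        metabolites=list(mets),
        reactions=rids,
        S=S,
        lb=np.array([r[2] for r in rxn_rows], float),
        ub=np.array([r[3] for r in rxn_rows], float),
        gpr=[r[4] for r in rxn_rows],
        genes=sorted(genes),
        objective_reaction=objective,
    )


def make_toy_network(kind: str) -> MetabolicModel:
    """Small well-formed test networks with GPR rules.

    * ``chain`` — uptake -> A -> B -> biomass; the uptake bound (10) caps the
      objective.
    * ``branched`` — two alternative internal routes (capacities 4 and 6,
      gated by distinct genes) from the uptake metabolite to the biomass
      precursor.
    * ``mini_tca`` — cit -> icit -> akg -> succ -> fum -> mal fragment with a
      citrate exchange and a malate-consuming maintenance objective.
    * ``glutathione`` — reduced/oxidized glutathione (gthrd <-> gthox, 2:1
      stoichiometry) and a 5-oxoproline branch, both feeding a maintenance
      objective through a cleared pool.
    """
    if kind == "chain":
        return _model(
            ["A", "B"],
            [
                ("uptake", {"A": 1}, 0, 10, ""),
                ("conv", {"A": -1, "B": 1}, 0, 1000, "g_ab"),
                ("biomass", {"B": -1}, 0, 1000, ""),
            ],
            "biomass",
        )
    if kind == "branched":
        return _model(
            ["A", "P"],
            [
                ("uptake", {"A": 1}, 0, 10, ""),
                ("route1", {"A": -1, "P": 1}, 0, 4, "g1"),
                ("route2", {"A": -1, "P": 1}, 0, 6, "g2"),
                ("biomass", {"P": -1}, 0, 1000, ""),
            ],
            "biomass",
        )
    if kind == "mini_tca":
        return _model(
            ["cit", "icit", "akg", "succ", "fum", "mal"],
            [
                ("EX_cit", {"cit": 1}, 0, 10, ""),
                ("ACONT", {"cit": -1, "icit": 1}, 0, 1000, "g_acont"),
                ("ICDH", {"icit": -1, "akg": 1}, 0, 1000, "g_icdh"),
                ("AKGD", {"akg": -1, "succ": 1}, 0, 1000, "g_akgd"),
                ("SUCD", {"succ": -1, "fum": 1}, 0, 1000, "g_sucd"),
                ("FUM", {"fum": -1, "mal": 1}, 0, 1000, "g_fum"),
                ("biomass", {"mal": -1}, 0, 1000, ""),
            ],
            "biomass",
        )
    if kind == "glutathione":
        return _model(
            ["gthrd", "gthox", "5oxpro", "clr"],
            [
                ("EX_gthrd", {"gthrd": 1}, 0, 10, ""),
                ("GTHOXID", {"gthrd": -2, "gthox": 1}, -1000, 1000, "g_gpx"),
                ("GTHDEG", {"gthox": -1, "clr": 1}, 0, 1000, "g_ggt"),
                ("OXPSYN", {"gthrd": -1, "5oxpro": 1}, 0, 1000, "g_oplah"),
                ("OXPDEG", {"5oxpro": -1, "clr": 1}, 0, 1000, "g_oxct"),
                ("biomass", {"clr": -1}, 0, 1000, ""),
            ],
            "biomass",
        )
    raise ValueError(f"unknown toy network kind {kind!r}")


TOY_NETWORK_KINDS = ("chain", "branched", "mini_tca", "glutathione")


def make_expression_profile(model: MetabolicModel, present_genes: set[str]) -> dict[str, float]:
    """Boolean protein presence: present genes map to 100, all others to 0."""
    extras = set(present_genes) - set(model.genes)
    if extras:
        warnings.warn(
            f"present genes not in the model are ignored: {sorted(extras)}", stacklevel=2
        )
    return {g: (100.0 if g in present_genes else 0.0) for g in model.genes}


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def write_cohort(
    spectra: Sequence[Spectrum], truth: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Emit spectra as per-sample TSVs plus metadata and ground-truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec_dir = outdir / "spectra"
    spec_dir.mkdir(exist_ok=True)
    meta_rows = []
    for s in spectra:
        sid = s.meta["sample_id"]
        write_spectrum_tsv(s, spec_dir / f"{sid}.tsv")
        meta_rows.append(
            {
                "sample_id": sid,
                "cell_line": s.meta.get("cell_line"),
                "source": s.meta.get("source"),
                "replicate": s.meta.get("replicate"),
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta_path = outdir / "metadata.csv"
    meta.to_csv(meta_path)
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, float_format="%.10g")
    return {"spectra_dir": spec_dir, "metadata": meta_path, "ground_truth": truth_path}
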