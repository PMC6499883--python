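"""End-to-end pipeline: simulate → acquire → reconstruct → preprocess →
STOCSY → chemometrics, with every intermediate written to an artifact
directory and a machine-readable run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import io as psio
from . import plotting
from .acquisition import (AcquisitionParams, PureShiftParams, acquire_pure_shift,
                          acquire_single_pulse, sapphire_average)
from .chemometrics import (coefficient_stocsy_overlay, crossval_q2,
                           hotelling_ellipse, pareto_scale, pls_da)
from .cohort import CohortDesign, default_design, simulate_concentrations
from .preprocessing import (DEFAULT_EXCLUSIONS, align, exclude_and_normalize,
                            matrix_from_spectra)
from .reconstruction import (PURE_SHIFT_PROCESSING, SINGLE_PULSE_PROCESSING,
                             ProcessingParams, assemble_chunks, process)
from .spin_systems import (Metabolite, MetaboliteLibrary, ProtonGroup,
                           default_library, save_library)
from .cohort import save_design
from .stocsy import stocsy_1d, stocsy_2d

log = logging.getLogger("pureshift")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline parameters; the defaults reproduce the study settings.

    500 MHz, 5 kHz / 2 K pure-shift direct dimension, 16 chunks of 39.063 Hz,
    8 SAPPHIRE increments with a compensation block, zero-fill to 32768 with
    a π/2-shifted sine bell (0.3 Hz exponential for the single-pulse
    spectra), residual-water exclusion 4.66–5.18 ppm, total-intensity
    normalization, full-resolution STOCSY with an r² display threshold of
    0.85, Pareto scaling, 3-component PLS-DA, 5-fold cross-validation.
    """

    seed: int = 1
    modes: tuple[str, ...] = ("single_pulse", "psyche", "sapphire")
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    psyche: PureShiftParams = field(default_factory=lambda: PureShiftParams(mode="psyche"))
    sapphire: PureShiftParams = field(default_factory=lambda: PureShiftParams(mode="sapphire"))
    single_pulse_processing: ProcessingParams = SINGLE_PULSE_PROCESSING
    pure_shift_processing: ProcessingParams = PURE_SHIFT_PROCESSING
    align_segments: int = 8
    align_max_shift: int = 0  # the simulator has no shift jitter by default
    exclusions: tuple = DEFAULT_EXCLUSIONS
    stocsy_threshold_r2: float = 0.85
    stocsy_drivers: tuple[float, ...] = (5.40, 3.03, 5.23)
    stocsy_2d_decimate: int = 64
    pls_components: int = 3
    cv_folds: int = 5
    chemometrics_mode: str = "sapphire"
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["modes"] = list(self.modes)
        d["exclusions"] = [list(r) for r in self.exclusions]
        d["stocsy_drivers"] = list(self.stocsy_drivers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionParams(**d["acquisition"])
        for key in ("psyche", "sapphire"):
            if key in d:
                d[key] = PureShiftParams(**d[key])
        for key in ("single_pulse_processing", "pure_shift_processing"):
            if key in d:
                d[key] = ProcessingParams(**d[key])
        if "modes" in d:
            d["modes"] = tuple(d["modes"])
        if "exclusions" in d:
            d["exclusions"] = tuple(tuple(r) for r in d["exclusions"])
        if "stocsy_drivers" in d:
            d["stocsy_drivers"] = tuple(d["stocsy_drivers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def parameter_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir,
                 design: CohortDesign | None = None,
                 library: MetaboliteLibrary | None = None) -> dict:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns a results dictionary with the in-memory objects of every stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = design or default_design()
    library = library or default_library()
    acq = replace(config.acquisition, seed=config.seed)
    results: dict = {"config": config}

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        s = stage("simulate")
        table = simulate_concentrations(design, config.seed)
        table.to_csv(out / "concentrations.csv")
        results["concentrations"] = table

        spectra_by_mode: dict[str, dict] = {}
        s = stage("acquire")
        if "single_pulse" in config.modes:
            fids = acquire_single_pulse(table, library, acq)
            psio.save_fids(fids, out / "fids_single_pulse.npz")
            spectra_by_mode["single_pulse"] = {
                sid: process(f, config.single_pulse_processing) for sid, f in fids.items()
            }
        for mode in ("psyche", "sapphire"):
            if mode not in config.modes:
                continue
            ps = getattr(config, mode)
            igs = acquire_pure_shift(table, library, acq, ps)
            psio.save_interferograms(igs, out / f"interferograms_{mode}.npz")
            spectra_by_mode[mode] = {
                sid: process(assemble_chunks(sapphire_average(ig)),
                             config.pure_shift_processing)
                for sid, ig in igs.items()
            }

        s = stage("reconstruct")
        for mode, spectra in spectra_by_mode.items():
            for sp in spectra.values():
                sp.mode = mode
            first = next(iter(spectra.values()))
            psio.write_spectrum_csv(first, out / f"spectrum_{mode}_{first.sample_id}.csv")
            psio.write_jcamp(first, out / f"spectrum_{mode}_{first.sample_id}.jdx",
                             title=f"{mode} {first.sample_id}")
        results["spectra"] = spectra_by_mode

        s = stage("preprocess")
        groups = dict(zip(table.sample_ids, table.groups))
        matrices = {}
        for mode, spectra in spectra_by_mode.items():
            m = matrix_from_spectra(spectra, groups)
            if config.align_max_shift > 0:
                m = align(m, config.align_segments, config.align_max_shift)
            m = exclude_and_normalize(m, config.exclusions)
            psio.save_matrix(m, out / f"matrix_{mode}.csv", out / f"matrix_{mode}.json")
            matrices[mode] = m
        results["matrices"] = matrices

        chem_mode = config.chemometrics_mode
        if chem_mode not in matrices:
            chem_mode = next(iter(matrices))
        mat = matrices[chem_mode]

        s = stage("stocsy")
        st2 = stocsy_2d(mat, config.stocsy_threshold_r2, config.stocsy_2d_decimate)
        st2.to_triplets().to_csv(out / f"stocsy2d_{chem_mode}.csv", index=False)
        stocsy1 = {}
        for drv in config.stocsy_drivers:
            s1 = stocsy_1d(mat, drv)
            s1.to_frame().to_csv(out / f"stocsy1d_{chem_mode}_{drv:.2f}ppm.csv",
                                 index=False)
            stocsy1[drv] = s1
            if config.make_plots:
                plotting.plot_stocsy_1d(s1, out / f"stocsy1d_{chem_mode}_{drv:.2f}ppm.png")
        if config.make_plots:
            plotting.plot_stocsy_2d(st2, out / f"stocsy2d_{chem_mode}.png")
        results["stocsy_2d"] = st2
        results["stocsy_1d"] = stocsy1

        s = stage("chemometrics")
        scaled, record = pareto_scale(mat.X)
        model = pls_da(scaled, mat.group_labels, config.pls_components, ppm=mat.ppm)
        cv = crossval_q2(scaled, mat.group_labels, config.pls_components,
                         config.cv_folds, config.seed)
        per_comp = {
            "component": list(range(1, config.pls_components + 1)),
            "R2X": model.r2x.tolist(), "R2Y": model.r2y.tolist(),
            "Q2": cv.q2.tolist(),
        }
        pd.DataFrame(per_comp).to_csv(out / f"pls_summary_{chem_mode}.csv", index=False)
        model.scores_frame().assign(sample=mat.sample_ids, group=mat.group_labels) \
            .to_csv(out / f"pls_scores_{chem_mode}.csv", index=False)
        ell = hotelling_ellipse(model.T[:, :2])
        overlay = coefficient_stocsy_overlay(model, stocsy1[config.stocsy_drivers[-1]], 1)
        overlay.to_csv(out / f"pls_overlay_{chem_mode}.csv", index=False)
        if config.make_plots:
            plotting.plot_scores(model, mat.group_labels,
                                 path=out / f"pls_scores_{chem_mode}.png")
            plotting.plot_overlay(overlay, config.stocsy_drivers[-1],
                                  path=out / f"pls_overlay_{chem_mode}.png")
        results.update(pls=model, cv=cv, ellipse=ell, overlay=overlay,
                       scaling=record)

        s = stage("manifest")
        from . import __version__
        manifest = {
            "seed": config.seed,
            "version": __version__,
            "parameter_hash": config.parameter_hash(),
            "modes": list(config.modes),
            "n_samples": len(table.sample_ids),
            "chemometrics_mode": chem_mode,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(s, str(exc)) from exc
    return results


# ---------------------------------------------------------------------------
# Canonical fixtures

FIXTURE_NAMES = ("doublet", "triplet", "two-metabolite", "cape-gooseberry-mini")


def fixture_library(name: str) -> MetaboliteLibrary:
    if name == "doublet":
        # partner placed 625 Hz (= 2 x 8/tau at the default chunking) from A so
        # its residual order-8k sidebands coincide with A's own sideband comb
        # instead of landing between measurement windows
        return MetaboliteLibrary([Metabolite("doublet", (
            ProtonGroup("A", 2.5, 1, (("B", 7.0),)),
            ProtonGroup("B", 1.25, 1, (("A", 7.0),)),
        ))])
    if name == "triplet":
        return MetaboliteLibrary([Metabolite("triplet", (
            ProtonGroup("A", 3.0, 1, (("B", 7.0),)),
            ProtonGroup("B", 1.2, 2, (("A", 7.0),)),
        ))])
    if name == "two-metabolite":
        return MetaboliteLibrary([
            Metabolite("met1", (
                ProtonGroup("A", 1.0, 1, (("B", 7.0),)),
                ProtonGroup("B", 2.0, 1, (("A", 7.0),)),
            )),
            Metabolite("met2", (
                ProtonGroup("A", 6.5, 1, (("B", 8.0),)),
                ProtonGroup("B", 7.5, 1, (("A", 8.0),)),
            )),
        ])
    if name == "cape-gooseberry-mini":
        return default_library()
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def fixture_design(name: str) -> CohortDesign:
    if name == "cape-gooseberry-mini":
        return default_design()
    lib = fixture_library(name)
    mets = lib.names
    return CohortDesign(
        groups=["A", "B"],
        replicates={"A": 5, "B": 5},
        mean_mM={m: 10.0 for m in mets},
        cv=0.2,
        group_multipliers={"B": {mets[0]: 1.3}},
    )


def make_fixtures(name: str, seed: int, outdir) -> list[Path]:
    """Write the canonical fixture inputs (library, design, concentrations)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lib = fixture_library(name)
    design = fixture_design(name)
    paths = [out / f"{name}-library.yaml", out / f"{name}-design.yaml",
             out / f"{name}-concentrations.csv"]
    save_library(lib, paths[0])
    save_design(design, paths[1])
    simulate_concentrations(design, seed).to_csv(paths[2])
    return paths
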