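"""Shared fixtures: canonical spin systems, noiseless acquisitions, and a
session-scoped run of the six-region synthetic cohort pipeline."""

from __future__ import annotations

import pytest

import pureshift as ps
from pureshift.cohort import CohortDesign, simulate_concentrations
from pureshift.pipeline import PipelineConfig, fixture_library, run_pipeline
from pureshift.spin_systems import Metabolite, MetaboliteLibrary, ProtonGroup


@pytest.fixture(scope="session")
def acq():
    """Noiseless 500 MHz acquisition with the study's pure-shift window."""
    return ps.AcquisitionParams()


@pytest.fixture(scope="session")
def doublet_lib():
    return fixture_library("doublet")


@pytest.fixture(scope="session")
def doublet_table(doublet_lib):
    design = CohortDesign(groups=["A"], replicates={"A": 1},
                          mean_mM={"doublet": 10.0}, cv=0.0)
    return simulate_concentrations(design, 1)


@pytest.fixture(scope="session")
def singlet_system():
    """Uncoupled one-group metabolite plus a single-sample table."""
    lib = MetaboliteLibrary([Metabolite("singlet", (ProtonGroup("A", 2.5, 1, ()),))])
    design = CohortDesign(groups=["A"], replicates={"A": 1},
                          mean_mM={"singlet": 10.0}, cv=0.0)
    return lib, simulate_concentrations(design, 1)


@pytest.fixture(scope="session")
def two_met_lib():
    return fixture_library("two-metabolite")


@pytest.fixture(scope="session")
def two_met_table(two_met_lib):
    """Independent concentrations for two well-separated metabolites."""
    design = CohortDesign(groups=["A", "B"], replicates={"A": 10, "B": 10},
                          mean_mM={"met1": 10.0, "met2": 8.0}, cv=0.3)
    return simulate_concentrations(design, 7)


def psyche_spectrum(table, lib, acq, mode="psyche", processing=None):
    """Acquire, average, assemble and process one sample's pure-shift spectrum."""
    pp = ps.PureShiftParams(mode=mode)
    igs = ps.acquire_pure_shift(table, lib, acq, pp)
    ig = next(iter(igs.values()))
    fid = ps.assemble_chunks(ps.sapphire_average(ig))
    return ps.process(fid, processing or ps.ProcessingParams()), ig


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """Full noiseless six-region cohort pipeline (the desk-scale study run)."""
    cfg = PipelineConfig(seed=1, make_plots=False)
    out = tmp_path_factory.mktemp("mini_run")
    return run_pipeline(cfg, out), out
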