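"""Chunk assembly, FT processing, peak picking, sidebands, quantitation."""

import numpy as np
import pytest

import pureshift as ps
from pureshift.cohort import CohortDesign, simulate_concentrations
from pureshift.reconstruction import Spectrum, integrate, sideband_offset
from pureshift.spin_systems import Metabolite, MetaboliteLibrary, ProtonGroup

from conftest import psyche_spectrum


def _table_for(lib, conc=10.0):
    design = CohortDesign(groups=["A"], replicates={"A": 1},
                          mean_mM={n: conc for n in lib.names}, cv=0.0)
    return simulate_concentrations(design, 1)


def _singlet_lib(shift=2.16):
    return MetaboliteLibrary([Metabolite("s", (ProtonGroup("A", shift, 1, ()),))])


# ---------------------------------------------------------------------------
# assemble_chunks


def test_assembled_length_is_chunks_times_points(singlet_system):
    lib, table = singlet_system
    acq = ps.AcquisitionParams(n_points=1024)
    pp = ps.PureShiftParams(mode="psyche", chunk_sw_hz=78.125)  # 64-point chunks
    ig = next(iter(ps.acquire_pure_shift(table, lib, acq, pp).values()))
    fid = ps.assemble_chunks(ig)
    assert fid.data.size == 16 * 64 == 1024


def test_multi_increment_assembly_refused(acq, singlet_system):
    lib, table = singlet_system
    ig = next(iter(ps.acquire_pure_shift(table, lib, acq,
                                         ps.PureShiftParams(mode="sapphire")).values()))
    with pytest.raises(ValueError, match="sapphire_average"):
        ps.assemble_chunks(ig)


def test_phase_continuity_across_chunk_boundaries(acq, singlet_system):
    """For a noiseless singlet the phase step across every chunk boundary is
    exactly one dwell of chemical-shift evolution, 2 pi nu / SW (mod 2 pi)."""
    lib, table = singlet_system
    ig = next(iter(ps.acquire_pure_shift(table, lib, acq,
                                         ps.PureShiftParams(mode="psyche")).values()))
    chunks = ig.data_chunks()[0]
    nu = (2.5 - acq.carrier_ppm) * acq.field_mhz
    expected = np.angle(np.exp(2j * np.pi * nu / acq.sw_hz))
    for k in range(chunks.shape[0] - 1):
        step = np.angle(chunks[k + 1, 0] / chunks[k, -1])
        assert step == pytest.approx(expected, abs=1e-9)


def test_compensation_block_positions(acq, singlet_system):
    lib, table = singlet_system
    for pos in ("prepend", "append"):
        pp = ps.PureShiftParams(mode="psyche", comp_position=pos)
        ig = next(iter(ps.acquire_pure_shift(table, lib, acq, pp).values()))
        fid = ps.assemble_chunks(ig)
        assert fid.data.size == 16 * 128


# ---------------------------------------------------------------------------
# process


def test_zero_fill_length_and_validation(acq, singlet_system):
    lib, table = singlet_system
    fid = next(iter(ps.acquire_single_pulse(table, lib, acq).values()))
    sp = ps.process(fid, ps.ProcessingParams(zero_fill=32768))
    assert sp.ppm.size == 32768
    with pytest.raises(ValueError, match="zero-fill"):
        ps.process(fid, ps.ProcessingParams(zero_fill=1024))


def test_processing_is_linear(acq, doublet_lib):
    table = _table_for(doublet_lib, 5.0)
    fid = next(iter(ps.acquire_single_pulse(table, doublet_lib, acq).values()))
    pp = ps.ProcessingParams()
    sp1 = ps.process(fid, pp)
    fid.data *= 3.0
    sp3 = ps.process(fid, pp)
    np.testing.assert_allclose(sp3.intensity, 3 * sp1.intensity,
                               rtol=0, atol=1e-9 * np.abs(sp1.intensity).max())


def test_singlet_peak_position_and_integral_proportionality():
    lib = _singlet_lib(2.16)
    acq = ps.AcquisitionParams(t2_s=0.05)
    pp = ps.ProcessingParams(apodization="none")
    sps = {}
    for conc in (5.0, 15.0):
        fid = next(iter(ps.acquire_single_pulse(_table_for(lib, conc), lib, acq).values()))
        sps[conc] = ps.process(fid, pp)
    for conc, sp in sps.items():
        peak = ps.peak_pick(sp, 0.5).nearest(2.16)
        assert abs(peak.position_ppm - 2.16) < sp.step_ppm
    i5 = integrate(sps[5.0], 2.0, 2.3)
    i15 = integrate(sps[15.0], 2.0, 2.3)
    assert i15 / i5 == pytest.approx(3.0, rel=1e-6)


def test_exponential_apodization_broadens_by_lb():
    """0.3 Hz exponential apodization widens the Lorentzian by 0.3 Hz (the
    convolution of two Lorentzians adds their widths)."""
    lib = _singlet_lib(2.5)
    acq = ps.AcquisitionParams(t2_s=0.05)
    fid = next(iter(ps.acquire_single_pulse(_table_for(lib), lib, acq).values()))

    def fwhm(pp):
        sp = ps.process(fid, pp)
        y = sp.intensity
        half = y.max() / 2
        idx = np.where(y >= half)[0]
        # linear interpolation at both half-height crossings
        lo, hi = idx[0], idx[-1]
        f = sp.hz_offset(sp.ppm)
        left = np.interp(half, [y[lo], y[lo - 1]], [f[lo], f[lo - 1]])
        right = np.interp(half, [y[hi], y[hi + 1]], [f[hi], f[hi + 1]])
        return abs(right - left)

    w0 = fwhm(ps.ProcessingParams(apodization="none"))
    w3 = fwhm(ps.ProcessingParams(apodization="exponential", lb_hz=0.3))
    assert w3 - w0 == pytest.approx(0.3, abs=0.03)


# ---------------------------------------------------------------------------
# peak picking


def test_flat_zero_spectrum_gives_empty_report():
    sp = Spectrum(np.linspace(5, 1, 100), np.zeros(100), 500.0, 4.7)
    assert len(ps.peak_pick(sp, 0.5)) == 0


def test_two_equal_maxima_both_reported():
    ppm = np.linspace(5, 1, 101)
    y = np.zeros(101)
    y[30] = y[70] = 1.0
    rep = ps.peak_pick(Spectrum(ppm, y, 500.0, 4.7), 0.5)
    assert len(rep) == 2


def test_plateau_tie_breaks_toward_lower_ppm():
    ppm = np.linspace(5, 1, 101)
    y = np.zeros(101)
    y[40:43] = 1.0  # flat-top plateau
    rep = ps.peak_pick(Spectrum(ppm, y, 500.0, 4.7), 0.5)
    assert len(rep) == 1
    assert rep.peaks[0].position_ppm == pytest.approx(ppm[42])  # lower ppm end


def test_peak_assignment_maps_nearest_expected():
    ppm = np.linspace(3, 1, 201)
    y = np.zeros(201)
    y[50] = 1.0
    rep = ps.peak_pick(Spectrum(ppm, y, 500.0, 4.7), 0.5,
                       expected={"glu": ppm[50] + 0.003})
    assert rep.assigned("glu").position_ppm == pytest.approx(ppm[50])


def test_invalid_threshold_rejected(singlet_system, acq):
    lib, table = singlet_system
    fid = next(iter(ps.acquire_single_pulse(table, lib, acq).values()))
    sp = ps.process(fid, ps.ProcessingParams())
    with pytest.raises(ValueError):
        ps.peak_pick(sp, 1.5)


# ---------------------------------------------------------------------------
# sidebands


def test_uncoupled_singlet_has_negligible_sidebands(acq, singlet_system):
    lib, table = singlet_system
    sp, ig = psyche_spectrum(table, lib, acq, "psyche")
    m = ps.sideband_metrics(sp, 2.5, ig.tau)
    assert m[(1, "+")] < 0.1 and m[(1, "-")] < 0.1


def test_sideband_windows_overlap_rejected(acq, singlet_system):
    lib, table = singlet_system
    sp, _ = psyche_spectrum(table, lib, acq, "psyche")
    with pytest.raises(ValueError, match="overlap"):
        ps.sideband_metrics(sp, 2.5, tau=1.0)  # 1 Hz spacing < 2x2 Hz windows


def test_sidebands_appear_at_multiples_of_chunk_rate(acq, doublet_lib, doublet_table):
    """Brute-force check of the artifact geometry: peaks at nu +/- q/tau."""
    pp = ps.ProcessingParams(apodization="gaussian", gb_hz=3.0, output="magnitude")
    sp, ig = psyche_spectrum(doublet_table, doublet_lib, acq, "psyche", pp)
    spacing = 1 / ig.tau
    rep = ps.peak_pick(sp, 1e-4)
    f_parent = float(sp.hz_offset(2.5))
    for q in (1, 2):
        for sgn in (+1, -1):
            target = f_parent + sgn * q * spacing
            got = min((float(sp.hz_offset(p.position_ppm)) for p in rep),
                      key=lambda x: abs(x - target))
            assert abs(got - target) < 0.6, (q, sgn)
    # and the dominant flanking artifact is the first-order sideband
    off = sideband_offset(sp, 2.5)
    assert off == pytest.approx(spacing, rel=0.02)


# ---------------------------------------------------------------------------
# quantitation comparison


def test_identical_spectra_zero_difference(acq, singlet_system):
    lib, table = singlet_system
    fid = next(iter(ps.acquire_single_pulse(table, lib, acq).values()))
    sp = ps.process(fid, ps.ProcessingParams())
    d = ps.compare_quantitation(sp, sp, {"s": (2.3, 2.7)})
    assert d["s"] == pytest.approx(0.0, abs=1e-12)


def test_global_attenuation_reads_as_uniform_loss(acq, two_met_lib):
    table = _table_for(two_met_lib)
    fid = next(iter(ps.acquire_single_pulse(table, two_met_lib, acq).values()))
    sp = ps.process(fid, ps.ProcessingParams())
    att = Spectrum(sp.ppm, 0.85 * sp.intensity, sp.field_mhz, sp.carrier_ppm)
    d = ps.compare_quantitation(sp, att, {"m1": (0.5, 2.5), "m2": (6.0, 8.0)})
    for v in d.values():
        assert v == pytest.approx(-15.0, abs=1e-9)


def test_ideal_pure_shift_conserves_window_integrals(acq, two_met_lib):
    """With windows wide enough to include the chunking sidebands, the ideal
    PSYCHE chunk model conserves multiplet integrals to within 2% (the J
    modulation redistributes amplitude between parent and sidebands but is
    unity at every chunk start)."""
    table = _table_for(two_met_lib)
    # a couple of Hz of broadening tames the truncation tails of the 1 s T2
    pp_proc = ps.ProcessingParams(apodization="exponential", lb_hz=2.0)
    fid_sp = next(iter(ps.acquire_single_pulse(table, two_met_lib, acq).values()))
    sp1 = ps.process(fid_sp, pp_proc)
    sp2, _ = psyche_spectrum(table, two_met_lib, acq, "psyche", pp_proc)
    regions = {"met1": (0.6, 2.4), "met2": (6.1, 7.9)}
    d = ps.compare_quantitation(sp1, sp2, regions)
    for v in d.values():
        assert abs(v) <= 2.0


def test_sapphire_parent_height_matches_psyche(acq, two_met_lib):
    """The zero-order Fourier coefficient of the chunk modulation is the same
    for every refocusing displacement, so SAPPHIRE averaging leaves the
    parent height of a J-coupled line equal to PSYCHE's within 1%."""
    table = _table_for(two_met_lib)
    pp_proc = ps.ProcessingParams(apodization="exponential", lb_hz=2.0)
    sp_p, _ = psyche_spectrum(table, two_met_lib, acq, "psyche", pp_proc)
    sp_s, _ = psyche_spectrum(table, two_met_lib, acq, "sapphire", pp_proc)
    for shift in (1.0, 6.5):
        hp = sp_p.intensity[sp_p.nearest_index(shift)]
        hs = sp_s.intensity[sp_s.nearest_index(shift)]
        assert hs / hp == pytest.approx(1.0, abs=0.01)


def test_window_outside_axis_rejected(acq, singlet_system):
    lib, table = singlet_system
    fid = next(iter(ps.acquire_single_pulse(table, lib, acq).values()))
    sp = ps.process(fid, ps.ProcessingParams())
    with pytest.raises(ValueError, match="outside"):
        ps.compare_quantitation(sp, sp, {"bad": (15.0, 16.0)})


# ---------------------------------------------------------------------------
# multiplet collapse


def test_multiplet_collapses_to_single_peak(acq):
    """A >10 Hz-wide triplet in the single-pulse spectrum becomes exactly one
    peak above threshold in the pure-shift spectrum."""
    lib = MetaboliteLibrary([Metabolite("t", (
        ProtonGroup("A", 3.0, 1, (("B", 7.0),)),
        ProtonGroup("B", 1.2, 2, (("A", 7.0),)),
    ))])
    table = _table_for(lib)
    fid = next(iter(ps.acquire_single_pulse(table, lib, acq).values()))
    sp1 = ps.process(fid, ps.ProcessingParams())
    sp2, _ = psyche_spectrum(table, lib, acq, "sapphire")

    def peaks_near(sp, centre, half=0.05):
        rep = ps.peak_pick(sp, 0.05)
        return [p for p in rep if abs(p.position_ppm - centre) < half]

    assert len(peaks_near(sp1, 3.0)) >= 3  # 1:2:1 triplet spans 14 Hz
    assert len(peaks_near(sp2, 3.0)) == 1
    assert abs(peaks_near(sp2, 3.0)[0].position_ppm - 3.0) < sp2.step_ppm
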