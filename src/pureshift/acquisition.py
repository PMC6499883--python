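"""Time-domain signal synthesis: single-pulse and chunked pure-shift FIDs.

The single-pulse model is the standard weak-coupling (first-order) one: each
proton group contributes a multiplet built from a binary splitting tree over
its partner couplings, every line decaying with a shared T2.

The chunked pure-shift model captures the one piece of physics the
interferogram methods hinge on: chemical-shift phase evolves continuously
through the reconstructed acquisition time, while J-coupling evolution is
refocused once per chunk and therefore restarts with period τ (the chunk
duration).  The periodic amplitude modulation cos(πJ·u)^n (u = time since
the last refocusing instant) is what throws sidebands at multiples of 1/τ
around every resonance.  SAPPHIRE displaces the refocusing instants by
p·τ/m across m phase increments, so the modulation of increment p is the
p·τ/m periodic translate of the PSYCHE modulation; each sideband order q
then carries an exact phase e^(−i2πqp/m) and the increment average cancels
orders 1..m−1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import ConcentrationTable
from .spin_systems import Metabolite, MetaboliteLibrary


@dataclass(frozen=True)
class AcquisitionParams:
    """Direct-dimension acquisition settings (500 MHz instrument defaults)."""

    field_mhz: float = 500.0
    sw_hz: float = 5000.0
    n_points: int = 2048
    carrier_ppm: float = 4.7
    t2_s: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    #: global pure-shift sensitivity factor (1.0 = no penalty)
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.sw_hz <= 0:
            raise ValueError("spectral width must be positive")
        if self.n_points < 2:
            raise ValueError("need at least 2 complex points")
        if self.t2_s <= 0:
            raise ValueError("T2 must be positive")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sw_hz

    def times(self, n: int | None = None) -> np.ndarray:
        return np.arange(self.n_points if n is None else n) * self.dwell_s


@dataclass(frozen=True)
class PureShiftParams:
    """Chunked (interferogram) acquisition settings.

    ``chunk_sw_hz`` is the F1 spectral width whose reciprocal is the chunk
    duration τ; the instrument-style default 39.063 Hz resolves to exactly
    128 samples (25.6 ms) at 5 kHz.  ``m_sapphire`` is the number of
    refocusing-point phase increments (1 ⇔ plain PSYCHE).
    """

    mode: str = "sapphire"  # "psyche" | "sapphire"
    n_chunks: int = 16
    chunk_sw_hz: float = 39.063
    m_sapphire: int | None = None
    compensation: bool = True
    comp_position: str = "prepend"  # "prepend" | "append"

    def __post_init__(self) -> None:
        if self.mode not in ("psyche", "sapphire"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.m_sapphire is None:
            object.__setattr__(self, "m_sapphire", 1 if self.mode == "psyche" else 8)
        if self.m_sapphire < 1:
            raise ValueError("m_sapphire must be >= 1")
        if self.mode == "psyche" and self.m_sapphire != 1:
            raise ValueError("PSYCHE mode requires m_sapphire = 1")
        if self.comp_position not in ("prepend", "append"):
            raise ValueError("comp_position must be 'prepend' or 'append'")

    def chunk_points(self, acq: AcquisitionParams) -> int:
        """Samples per chunk; the nominal τ·SW must be an integer within 0.5%."""
        exact = acq.sw_hz / self.chunk_sw_hz
        n = int(round(exact))
        if n < 1 or abs(exact - n) > 0.01:
            raise ValueError(
                f"chunk width {self.chunk_sw_hz} Hz does not divide SW {acq.sw_hz} Hz "
                f"into an integer sample count (tau*SW = {exact:.4f})"
            )
        return n

    def tau(self, acq: AcquisitionParams) -> float:
        """Effective chunk duration (s), exact on the sampling grid."""
        return self.chunk_points(acq) / acq.sw_hz


@dataclass(frozen=True)
class Transition:
    freq_hz: float
    amplitude: float
    metabolite: str
    group: str


@dataclass
class TransitionList:
    """First-order multiplet lines for one metabolite at one concentration."""

    transitions: list[Transition]

    def __iter__(self):
        return iter(self.transitions)

    def __len__(self) -> int:
        return len(self.transitions)

    @property
    def freqs(self) -> np.ndarray:
        return np.array([t.freq_hz for t in self.transitions])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([t.amplitude for t in self.transitions])

    def group_amplitude(self, group: str) -> float:
        return sum(t.amplitude for t in self.transitions if t.group == group)


@dataclass
class Fid:
    """Complex free-induction decay on the uniform grid t_n = n/SW."""

    data: np.ndarray
    params: AcquisitionParams
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.shape != (self.params.n_points,):
            raise ValueError(
                f"FID length {self.data.shape} != declared points {self.params.n_points}"
            )


@dataclass
class Interferogram:
    """Pure-shift chunks indexed (phase increment p, chunk slot, local point).

    ``data`` has shape (m, n_stored, chunk_points) where n_stored includes
    the optional compensation chunk (bookkeeping only; reconstruction skips
    it).  ``data_chunks()`` returns the n_chunks signal chunks in
    global-time order.
    """

    data: np.ndarray
    acq: AcquisitionParams
    ps: PureShiftParams
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        npts = self.ps.chunk_points(self.acq)
        n_stored = self.ps.n_chunks + (1 if self.ps.compensation else 0)
        if self.data.shape != (self.ps.m_sapphire, n_stored, npts):
            raise ValueError(
                f"interferogram shape {self.data.shape} != "
                f"({self.ps.m_sapphire}, {n_stored}, {npts})"
            )

    @property
    def tau(self) -> float:
        return self.ps.tau(self.acq)

    @property
    def n_increments(self) -> int:
        return self.data.shape[0]

    def data_chunks(self) -> np.ndarray:
        """(m, n_chunks, chunk_points) with the compensation chunk dropped."""
        if not self.ps.compensation:
            return self.data
        if self.ps.comp_position == "prepend":
            return self.data[:, 1:, :]
        return self.data[:, :-1, :]


# ---------------------------------------------------------------------------
# Multiplet construction


def transitions(metabolite: Metabolite, concentration_mM: float,
                acq: AcquisitionParams) -> TransitionList:
    """First-order multiplet lines of one metabolite.

    Each partner group with n equivalent protons contributes n successive
    ±J/2 splits (binomial weights); line frequency is the carrier-relative
    shift plus the accumulated ±J/2 offsets, and the amplitudes of a group's
    lines sum to concentration × n_equiv.
    """
    out: list[Transition] = []
    for g in metabolite.groups:
        nu0 = (g.shift_ppm - acq.carrier_ppm) * acq.field_mhz
        lines: dict[float, float] = {0.0: 1.0}
        for partner_label, j in g.couplings:
            n_partner = metabolite.group(partner_label).n_equiv
            for _ in range(n_partner):
                nxt: dict[float, float] = {}
                for off, w in lines.items():
                    for s in (+0.5, -0.5):
                        key = round(off + s * j, 9)
                        nxt[key] = nxt.get(key, 0.0) + 0.5 * w
                lines = nxt
        amp0 = concentration_mM * g.n_equiv
        for off, w in sorted(lines.items()):
            out.append(Transition(nu0 + off, amp0 * w, metabolite.name, g.label))
    return TransitionList(out)


def _sample_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _collect_lines(sample_conc: dict[str, float], lib: MetaboliteLibrary,
                   acq: AcquisitionParams):
    freqs, amps = [], []
    for met_name, conc in sample_conc.items():
        tl = transitions(lib.lookup(met_name), conc, acq)
        freqs.append(tl.freqs)
        amps.append(tl.amplitudes)
    return np.concatenate(freqs), np.concatenate(amps)


def acquire_single_pulse(table: ConcentrationTable, lib: MetaboliteLibrary,
                         acq: AcquisitionParams) -> dict[str, Fid]:
    """Simulate a conventional hard-pulse ¹H FID for every sample."""
    t = acq.times()
    decay = np.exp(-t / acq.t2_s)
    rngs = _sample_rngs(acq.seed, len(table.sample_ids))
    out: dict[str, Fid] = {}
    for rng, sid in zip(rngs, table.sample_ids):
        freqs, amps = _collect_lines(table.sample(sid), lib, acq)
        x = (np.exp(2j * np.pi * np.outer(t, freqs)) @ amps) * decay
        if acq.noise_sigma > 0:
            x = x + acq.noise_sigma * (rng.standard_normal(len(t))
                                       + 1j * rng.standard_normal(len(t)))
        out[sid] = Fid(x, acq, sid)
    return out


def _decoupled_lines(sample_conc: dict[str, float], lib: MetaboliteLibrary,
                     acq: AcquisitionParams):
    """Per proton group: centre frequency, total amplitude, [(J, n_partner)]."""
    nus, amps, couplings = [], [], []
    for met_name, conc in sample_conc.items():
        m = lib.lookup(met_name)
        for g in m.groups:
            nus.append((g.shift_ppm - acq.carrier_ppm) * acq.field_mhz)
            amps.append(conc * g.n_equiv)
            couplings.append([(j, m.group(p).n_equiv) for p, j in g.couplings])
    return np.array(nus), np.array(amps), couplings


def acquire_pure_shift(table: ConcentrationTable, lib: MetaboliteLibrary,
                       acq: AcquisitionParams, ps: PureShiftParams) -> dict[str, Interferogram]:
    """Simulate a chunked pure-shift interferogram for every sample.

    Chunk (p, k), local time δ, global time t = kτ + δ:

        s(p, k, δ) = Σ_groups a·exp(i2πν₀t)·Π_j cos(πJ_j·u_p(δ))^{n_j}·exp(−t/T2)

    with u_p(δ) = (δ − pτ/m) mod τ, the time elapsed since the nearest
    preceding J-refocusing instant (instants sit at pτ/m + integer·τ; the
    one before the first chunk is what the compensation block pays for).
    Chemical-shift phase is continuous in t; J modulation is periodic with
    period τ — the sideband mechanism.  Noise is drawn independently per
    chunk and per increment (each increment is a separate scan set).
    """
    npts = ps.chunk_points(acq)
    tau = ps.tau(acq)
    m = ps.m_sapphire
    delta = np.arange(npts) / acq.sw_hz
    n_stored = ps.n_chunks + (1 if ps.compensation else 0)

    rngs = _sample_rngs(acq.seed ^ 0x5A11, len(table.sample_ids))
    out: dict[str, Interferogram] = {}
    t_full = np.arange(ps.n_chunks * npts) / acq.sw_hz
    for rng, sid in zip(rngs, table.sample_ids):
        nus, amps, coup = _decoupled_lines(table.sample(sid), lib, acq)
        amps = amps * acq.attenuation
        phase = np.exp(2j * np.pi * np.outer(t_full, nus))  # (T, G)
        decay = np.exp(-t_full / acq.t2_s)
        data = np.empty((m, n_stored, npts), dtype=complex)
        for p in range(m):
            u = np.mod(delta - p * tau / m, tau)  # J evolution time within chunk
            # rounding can land a refocusing instant at tau - eps instead of 0
            u[u > tau * (1 - 1e-9)] -= tau
            mods = np.ones((npts, len(nus)))
            for gi, cl in enumerate(coup):
                for j, n_eq in cl:
                    mods[:, gi] *= np.cos(np.pi * j * u) ** n_eq
            x = ((phase * np.tile(mods, (ps.n_chunks, 1))) @ amps) * decay
            chunks = x.reshape(ps.n_chunks, npts)
            if ps.compensation:
                comp = chunks[:1] if ps.comp_position == "prepend" else chunks[-1:]
                stack = ([comp, chunks] if ps.comp_position == "prepend" else [chunks, comp])
                block = np.concatenate(stack, axis=0)
            else:
                block = chunks
            if acq.noise_sigma > 0:
                block = block + acq.noise_sigma * (
                    rng.standard_normal(block.shape) + 1j * rng.standard_normal(block.shape)
                )
            data[p] = block
        out[sid] = Interferogram(data, acq, ps, sid)
    return out


def sapphire_average(ig: Interferogram) -> Interferogram:
    """Average the phase increments chunk-wise; the result has m = 1.

    With the refocusing instants displaced by pτ/m, the modulation of
    increment p is a periodic translate of the p = 0 modulation, so the mean
    over p annihilates sideband Fourier orders 1..m−1 exactly (noiseless).
    For m = 1 this is the identity.
    """
    mean = ig.data.mean(axis=0, keepdims=True)
    return Interferogram(mean, ig.acq, replace(ig.ps, m_sapphire=1), ig.sample_id)
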