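"""Construction of RAFFn pulse packets, stretched RAFF2 packets and comparison pulses.

RAFFn (Relaxation Along a Fictitious Field in the rotating frame of rank n)
irradiation uses amplitude- and frequency-modulated pulses operated below the
adiabatic condition.  For rank 2 the modulation functions are

    omega_1(t) = omega_1^max * sin(omega_1^max * t)
    d_omega(t) = omega_1^max * cos(omega_1^max * t)

so the first-frame effective field has constant magnitude omega_1^max and is
swept at the constant rate omega_1^max; the fictitious field seen in the
second rotating frame is then stationary, tilted at alpha_2 = 45 deg, with
magnitude sqrt(2)*omega_1^max.  An element of duration

    T_e = pi / (sqrt(2) * omega_1^max)

rotates the magnetization by exactly pi about that fictitious field, and four
elements P, P_pi^-1, P_pi, P^-1 (time reversal with negated frequency offset;
pi phase shift on the middle pair) form a rotating-frame rotary echo, the
"P-packet", of duration 4*pi/(sqrt(2)*omega_1^max) (2.26 ms at 625 Hz).

A stretching factor TL rescales the element duration (TL = 0.6 compresses,
TL = 2.0 doubles) while the modulation frequency stays at the nominal design
value, so the sweep angle covered by an element grows in proportion to TL and
the second-frame tilt remains at 45 deg for every TL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

TWO_PI = 2.0 * np.pi

#: Nominal peak RF amplitude of the reference RAFF2 pulse (Hz).
NOMINAL_PEAK_HZ = 625.0

#: Default number of waveform samples per P-packet.
PACKET_SAMPLES = 128

#: Published per-TL presets: peak amplitude (Hz), packet length (ms),
#: refocusing (element) length (ms).  The TL0.6 entry uses the reduced
#: 608 Hz amplitude of the instrument preset; TL2.0 carries a rounded
#: 4.55 ms where exact linear scaling gives 4.53 ms.
RAFF2_TL_PRESETS = {
    0.6: {"peak_hz": 608.0, "packet_ms": 1.35, "refocusing_ms": 0.34},
    0.8: {"peak_hz": 625.0, "packet_ms": 1.80, "refocusing_ms": 0.45},
    1.0: {"peak_hz": 625.0, "packet_ms": 2.25, "refocusing_ms": 0.57},
    1.2: {"peak_hz": 625.0, "packet_ms": 2.70, "refocusing_ms": 0.68},
    1.4: {"peak_hz": 625.0, "packet_ms": 3.15, "refocusing_ms": 0.79},
    1.6: {"peak_hz": 625.0, "packet_ms": 3.60, "refocusing_ms": 0.90},
    1.8: {"peak_hz": 625.0, "packet_ms": 4.05, "refocusing_ms": 1.01},
    2.0: {"peak_hz": 625.0, "packet_ms": 4.55, "refocusing_ms": 1.14},
}


def element_duration(TL: float, design_hz: float = NOMINAL_PEAK_HZ) -> float:
    """Duration of a single refocusing element in seconds."""
    return TL * np.pi / (np.sqrt(2.0) * TWO_PI * design_hz)


def packet_duration(TL: float, design_hz: float = NOMINAL_PEAK_HZ) -> float:
    """Duration of the four-element P-packet: TL * 4*pi/(sqrt2 * w1max)."""
    return 4.0 * element_duration(TL, design_hz)


@dataclass
class RFShape:
    """A sampled RF waveform, uniform in time (midpoint sample convention).

    Two equivalent representations are carried:

    * amplitude (rad/s, >= 0) with ``carrier`` phase (rad) and frequency
      ``offsets`` (rad/s) -- the native form for amplitude/frequency
      modulated pulses, where the offset acts as a longitudinal field;
    * amplitude with the total unwrapped ``phase`` track, where the offset
      has been folded into the phase by the midpoint cumulative rule
      phi_i = carrier_i + dt * (sum_{j<i} dw_j + dw_i/2).

    ``frequency_offsets`` inverts the folding exactly, so the forms
    interconvert losslessly.
    """

    amplitude: np.ndarray
    offsets: np.ndarray
    dt: float
    carrier: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.amplitude.ndim != 1 or self.amplitude.shape != self.offsets.shape:
            raise ValueError("amplitude and offsets must be 1-D arrays of equal length")
        if self.amplitude.size == 0:
            raise ValueError("RFShape must contain at least one sample")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.carrier is None:
            self.carrier = np.zeros_like(self.amplitude)
        else:
            self.carrier = np.broadcast_to(
                np.asarray(self.carrier, dtype=float), self.amplitude.shape
            ).copy()
        # fold negative amplitudes into a pi carrier flip
        neg = self.amplitude < 0
        if np.any(neg):
            self.amplitude = np.abs(self.amplitude)
            self.carrier = self.carrier + np.pi * neg

    @property
    def n_samples(self) -> int:
        return self.amplitude.size

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(self.amplitude))

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) + 0.5) * self.dt

    @property
    def phase(self) -> np.ndarray:
        """Total unwrapped phase with the offset track folded in."""
        cum = np.concatenate([[0.0], np.cumsum(self.offsets)])
        return self.carrier + self.dt * (cum[:-1] + self.offsets / 2.0)

    def frequency_offsets(self) -> np.ndarray:
        return self.offsets

    @classmethod
    def from_amp_phase(
        cls, amplitude: np.ndarray, phase: np.ndarray, dt: float, label: str = ""
    ) -> "RFShape":
        """Reconstruct a shape from the (amplitude, total phase) form.

        The inverse of the midpoint folding with zero carrier:
        dw_0 = 2 phi_0 / dt, dw_{i+1} = 2 (phi_{i+1} - phi_i)/dt - dw_i.
        """
        phase = np.asarray(phase, dtype=float)
        amplitude = np.asarray(amplitude, dtype=float)
        w = np.empty_like(phase)
        w[0] = 2.0 * phase[0] / dt
        d = np.diff(phase) / dt
        for i in range(1, w.size):
            w[i] = 2.0 * d[i - 1] - w[i - 1]
        return cls(amplitude, w, dt, label=label)


@dataclass
class PPacket:
    """The four-element rotary-echo packet P, P_pi^-1, P_pi, P^-1."""

    elements: Sequence[RFShape]
    TL: float
    omega1max: float  # rad/s, played peak amplitude
    rank: int
    alpha1: float = 45.0  # deg
    alpha2: float = 45.0  # deg

    def __post_init__(self) -> None:
        if len(self.elements) != 4:
            raise ValueError("a P-packet consists of exactly 4 elements")

    @property
    def omega1max_hz(self) -> float:
        return self.omega1max / TWO_PI

    @property
    def element_duration(self) -> float:
        return self.elements[0].duration

    @property
    def packet_duration(self) -> float:
        return sum(e.duration for e in self.elements)

    @property
    def n_samples(self) -> int:
        return sum(e.n_samples for e in self.elements)

    def concatenated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """(amplitude, offset, carrier) sample arrays over the packet, and dt."""
        amp = np.concatenate([e.amplitude for e in self.elements])
        off = np.concatenate([e.offsets for e in self.elements])
        car = np.concatenate([e.carrier for e in self.elements])
        return amp, off, car, self.elements[0].dt


@dataclass
class PulseTrain:
    """A train of identical P-packets."""

    packet: PPacket
    n_packets: int

    def __post_init__(self) -> None:
        if self.n_packets < 0:
            raise ValueError("n_packets must be >= 0")

    @property
    def total_duration(self) -> float:
        return self.n_packets * self.packet.packet_duration

    @property
    def boundary_times(self) -> np.ndarray:
        return np.arange(self.n_packets + 1) * self.packet.packet_duration


def _rotary_echo_elements(
    w1: np.ndarray, dw: np.ndarray, dt: float, tag: str
) -> list[RFShape]:
    """Assemble P, P_pi^-1, P_pi, P^-1 from one forward element.

    Inverse elements are the time-reversed sample sequence with negated
    frequency offset; the middle pair carries a pi carrier-phase shift.
    With this pairing U(P_pi^-1) = U(P)^-1 holds sample-by-sample, so the
    packet is an exact rotary echo at any discretization.
    """
    w1r, dwr = w1[::-1], -dw[::-1]
    return [
        RFShape(w1, dw, dt, carrier=0.0, label=f"{tag}:P"),
        RFShape(w1r, dwr, dt, carrier=np.pi, label=f"{tag}:P_pi^-1"),
        RFShape(w1, dw, dt, carrier=np.pi, label=f"{tag}:P_pi"),
        RFShape(w1r, dwr, dt, carrier=0.0, label=f"{tag}:P^-1"),
    ]


def make_raff2_packet(
    omega1max_hz: float,
    TL: float,
    n_samples: int = PACKET_SAMPLES,
    design_hz: float = NOMINAL_PEAK_HZ,
) -> PPacket:
    """Build a (possibly stretched) rank-2 P-packet.

    Parameters
    ----------
    omega1max_hz:
        Peak RF amplitude in Hz (the played pulse power).
    TL:
        Stretching factor; TL = 1 is the 2.25 ms reference packet.
    n_samples:
        Samples per packet, divisible by 4 (default 32 per element).
    design_hz:
        Nominal design frequency fixing the time grid and modulation
        frequency.  The packet duration is TL * 4*pi/(sqrt2 * 2*pi*design_hz)
        regardless of the played amplitude, mirroring preset pulse shapes
        whose power is calibrated independently of their length.
    """
    if omega1max_hz <= 0:
        raise ValueError(f"omega1max_hz must be positive, got {omega1max_hz}")
    if TL <= 0:
        raise ValueError(f"TL must be positive, got {TL}")
    if n_samples % 4 != 0 or n_samples <= 0:
        raise ValueError(f"n_samples must be a positive multiple of 4, got {n_samples}")

    A = TWO_PI * omega1max_hz
    wm = TWO_PI * design_hz  # modulation frequency, fixed across TL
    Te = element_duration(TL, design_hz)
    ns = n_samples // 4
    dt = Te / ns
    t = (np.arange(ns) + 0.5) * dt
    w1 = A * np.sin(wm * t)
    dw = A * np.cos(wm * t)
    elements = _rotary_echo_elements(w1, dw, dt, tag=f"RAFF2-TL{TL:g}")
    return PPacket(elements=elements, TL=TL, omega1max=A, rank=2)


def _raffn_modulations(
    rank: int, omega1max: float, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-recursion modulation tracks for rank >= 2.

    The rank-n pulse keeps the n-th-frame fictitious field stationary at
    45 deg with magnitude sqrt(2)*omega1max by sweeping the (n-1)-frame tilt
    at the constant rate omega1max.  Descending one frame at a time:
    E_{k-1}(t) = E_k(t) cos(alpha_k(t)),
    d(alpha_{k-1})/dt = E_k(t) sin(alpha_k(t)).
    """
    E = np.full_like(t, omega1max)
    alpha = omega1max * t
    dt = t[1] - t[0] if t.size > 1 else 0.0
    for _ in range(rank - 2):
        dalpha = E * np.sin(alpha)
        E = E * np.cos(alpha)
        cum = np.concatenate([[0.0], np.cumsum(dalpha)])
        alpha = dt * (cum[:-1] + dalpha / 2.0)
    return E * np.sin(alpha), E * np.cos(alpha)


def make_raffn_packet(
    rank: int,
    omega1max_hz: float = NOMINAL_PEAK_HZ,
    n_samples: int = PACKET_SAMPLES,
) -> PPacket:
    """Build a rank-n (n = 1..5) P-packet at TL = 1.

    rank = 2 reproduces :func:`make_raff2_packet` at TL = 1; rank = 1 is the
    constant 45-deg effective field (equal amplitude and offset); ranks 3-5
    apply the downward frame recursion, under which the peak played
    amplitude is non-increasing with rank.
    """
    if rank not in (1, 2, 3, 4, 5):
        raise ValueError(f"rank must be in 1..5, got {rank}")
    if rank == 2:
        return make_raff2_packet(omega1max_hz, 1.0, n_samples, design_hz=omega1max_hz)

    A = TWO_PI * omega1max_hz
    Te = element_duration(1.0, omega1max_hz)
    ns = n_samples // 4
    dt = Te / ns
    t = (np.arange(ns) + 0.5) * dt
    if rank == 1:
        w1 = np.full(ns, A)
        dw = np.full(ns, A)
    else:
        w1, dw = _raffn_modulations(rank, A, t)
    elements = _rotary_echo_elements(w1, dw, dt, tag=f"RAFF{rank}")
    return PPacket(elements=elements, TL=1.0, omega1max=A, rank=rank)


def build_train(packet: PPacket, n_packets: int) -> PulseTrain:
    """A train of ``n_packets`` identical packets (0 gives an empty train)."""
    if n_packets < 0:
        raise ValueError(f"n_packets must be >= 0, got {n_packets}")
    return PulseTrain(packet=packet, n_packets=int(n_packets))


COMPARISON_KINDS = ("CW_SL", "AHP", "HS1", "HS4", "HARD")


def make_comparison_pulse(
    kind: str,
    duration: float,
    peak_hz: float,
    truncation_R: float = 20.0,
    n_samples: int = 256,
    bandwidth_hz: float | None = None,
) -> RFShape:
    """Comparison pulses used alongside the RAFFn trains.

    CW_SL  constant-amplitude spin lock, zero offset.
    HARD   constant-amplitude, zero-phase rectangular pulse.
    HS1    hyperbolic-secant adiabatic full passage: sech amplitude with a
           tanh frequency sweep, truncated at sech = 1/R.
    HS4    stretched variant: sech(beta*tau^4) amplitude with the matched
           integrated-sech^2 sweep.
    AHP    adiabatic half passage: the first half of an HS1 sweep, ending
           with the effective field in the transverse plane.
    """
    if kind not in COMPARISON_KINDS:
        raise ValueError(f"unknown pulse kind {kind!r}; expected one of {COMPARISON_KINDS}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if peak_hz <= 0:
        raise ValueError(f"peak_hz must be positive, got {peak_hz}")

    A = TWO_PI * peak_hz
    dt = duration / n_samples
    tm = (np.arange(n_samples) + 0.5) * dt

    if kind in ("CW_SL", "HARD"):
        return RFShape(np.full(n_samples, A), np.zeros(n_samples), dt, label=kind)

    beta = np.arccosh(truncation_R)
    bw = TWO_PI * (bandwidth_hz if bandwidth_hz is not None else peak_hz)
    if kind == "AHP":
        tau = tm / duration - 1.0  # [-1, 0]: half passage ending on resonance
        w1 = A / np.cosh(beta * tau)
        dw = -bw * np.tanh(beta * tau) / np.tanh(beta)
        return RFShape(w1, dw, dt, label=kind)
    tau = 2.0 * tm / duration - 1.0  # [-1, 1]
    power = 1 if kind == "HS1" else 4
    w1 = A / np.cosh(beta * np.abs(tau) ** power)
    sech2 = 1.0 / np.cosh(beta * np.abs(tau) ** power) ** 2
    cum = np.concatenate([[0.0], np.cumsum(sech2)])
    sweep = cum[:-1] + sech2 / 2.0
    sweep = sweep - sweep[-1] / 2.0  # centre the sweep at mid-pulse
    dw = bw * sweep / np.abs(sweep[-1])
    return RFShape(w1, dw, dt, label=kind)
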