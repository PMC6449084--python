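"""Synthetic whole-cell membrane-potential sweeps.

A sweep is a resting level plus, for every motor cycle, a raised-cosine
depolarisation bump whose amplitude is given by a recruitment rule as a
function of the cycle frequency; spikes are inserted where the bump
exceeds the spike threshold.  Hyperpolarising current steps produce a
passive RC response, so input resistance can be recovered by Ohm's law.
"""

from __future__ import annotations

import numpy as np

from zfswim.ephys import VmSweep

__all__ = ["make_vm_sweep", "threshold_rule"]


def threshold_rule(cutoff_hz: float = 35.0, depol_mv: float = 25.0, below_mv: float = 2.0):
    """Recruitment rule firing only above a cycle-frequency cutoff."""

    def rule(freq_hz: float) -> float:
        return depol_mv if freq_hz > cutoff_hz else below_mv

    return rule


def make_vm_sweep(
    cycles: list[tuple[float, float]],
    recruitment_rule,
    seed: int,
    *,
    fs: float = 10000.0,
    duration_s: float | None = None,
    rest_mv: float = -65.0,
    spike_threshold_mv: float = -45.0,
    spike_peak_mv: float = 20.0,
    spike_width_s: float = 0.0015,
    noise_sd_mv: float = 0.0,
    current_steps: list[tuple[float, float, float]] | None = None,
    r_m_mohm: float = 100.0,
    c_m_pf: float = 100.0,
) -> VmSweep:
    """Build a Vm sweep from cycle times and a recruitment rule.

    ``cycles`` is a time-ordered list of (start_s, freq_hz); each cycle
    spans 1/freq.  ``recruitment_rule(freq)`` returns the subthreshold
    depolarisation amplitude in mV.  Spikes (triangular, ~1.5 ms) are
    added near the bump peak when the depolarised Vm would exceed the
    spike threshold, one extra spike per 4 mV of overshoot.  Current
    steps add a passive RC response with R = ``r_m_mohm`` and
    τ = R·C.
    """
    if any(b[0] < a[0] for a, b in zip(cycles, cycles[1:])):
        raise ValueError("cycles must be time-ordered")
    if duration_s is None:
        last = max([c[0] + 1.0 / c[1] for c in cycles], default=0.5)
        step_end = max([s[1] + s[2] for s in (current_steps or [])], default=0.0)
        duration_s = max(last, step_end) + 0.3
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    vm = np.full(n, rest_mv)

    for start, freq in cycles:
        period = 1.0 / freq
        amp = float(recruitment_rule(freq))
        i0 = int(round(start * fs))
        i1 = min(int(round((start + period) * fs)), n)
        if i1 <= i0:
            continue
        phase = np.linspace(0, 2 * np.pi, i1 - i0)
        bump = 0.5 * amp * (1 - np.cos(phase))
        vm[i0:i1] += bump
        overshoot = (rest_mv + amp) - spike_threshold_mv
        if overshoot > 0:
            n_spikes = 1 + int(overshoot // 4.0)
            centre = (i0 + i1) // 2
            span = max((i1 - i0) // 4, 1)
            locs = np.linspace(centre - span, centre + span, n_spikes).astype(int)
            half = max(int(spike_width_s * fs / 2), 1)
            for c in locs:
                lo, hi = max(c - half, 0), min(c + half + 1, n)
                tri = 1.0 - np.abs(np.arange(lo, hi) - c) / half
                target = spike_peak_mv - vm[c]
                vm[lo:hi] += np.clip(tri, 0, 1) * target

    tau = r_m_mohm * 1e6 * c_m_pf * 1e-12  # seconds
    for amp_pa, onset, width in current_steps or []:
        dv_inf = amp_pa * r_m_mohm * 1e-3  # pA × MΩ → mV
        on = t >= onset
        during = on & (t < onset + width)
        after = t >= onset + width
        vm[during] += dv_inf * (1 - np.exp(-(t[during] - onset) / tau))
        v_end = dv_inf * (1 - np.exp(-width / tau))
        vm[after] += v_end * np.exp(-(t[after] - onset - width) / tau)

    if noise_sd_mv > 0:
        vm += rng.normal(0, noise_sd_mv, n)
    return VmSweep(
        vm=vm, fs=fs, spike_threshold=spike_threshold_mv,
        current_steps=list(current_steps or []),
    )
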