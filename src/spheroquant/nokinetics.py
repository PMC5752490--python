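"""First-order NONOate decomposition and quasi-steady NO levels.

NONOate donors such as DETA/NO decompose spontaneously in aqueous media with
first-order kinetics (half-life ≈ 24 h at pH 7.4, 37 °C), releasing ν = 2 mol
NO per mol of parent compound. In culture medium NO is consumed rapidly; with
consumption modelled as a single first-order sink with rate k_c, the
quasi-steady NO concentration is

    [NO]_ss = ν · k_d · D0 / k_c,      k_d = ln 2 / t½,

which is exactly linear in the donor dose D0. k_c is not predicted from
mechanism but calibrated from one measured reference pair (here 100 µM donor
→ 100 nM NO), after which the model reproduces that pair exactly and scales
linearly to other doses (1 µM → 1 nM). The approximation holds for t ≪ t½,
while the donor pool is effectively undepleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DonorModel"]


@dataclass
class DonorModel:
    """First-order NO-donor model.

    Parameters
    ----------
    d0_um : initial donor concentration, µM (≥ 0).
    half_life_h : donor half-life, hours (default 24, DETA/NO at pH 7.4/37 °C).
    no_yield : mol NO released per mol donor (default 2 for NONOates).
    k_c_per_h : first-order NO consumption rate (1/h); set by calibration.
    """

    d0_um: float
    half_life_h: float = 24.0
    no_yield: float = 2.0
    k_c_per_h: float | None = None

    def __post_init__(self) -> None:
        if self.d0_um < 0:
            raise ValueError("d0_um must be >= 0")
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if self.k_c_per_h is not None and self.k_c_per_h <= 0:
            raise ValueError("k_c_per_h must be > 0")

    @property
    def decay_rate_per_h(self) -> float:
        """First-order donor decay constant k_d = ln2 / t½ (1/h)."""
        return math.log(2.0) / self.half_life_h

    def donor_remaining(self, t_hours: float) -> float:
        """Remaining donor D(t) = D0 · 2^(−t/t½), µM, for t ≥ 0."""
        if t_hours < 0:
            raise ValueError("t must be >= 0")
        return self.d0_um * 2.0 ** (-t_hours / self.half_life_h)

    def cumulative_no(self, t_hours: float) -> float:
        """Total NO released up to t: ν · (D0 − D(t)), µM NO equivalents."""
        return self.no_yield * (self.d0_um - self.donor_remaining(t_hours))

    def calibrate_kc(self, d_ref_um: float, no_ref_nm: float) -> float:
        """Fix k_c so that a reference donor dose maps to a measured NO level.

        k_c = ν · k_d · D_ref / [NO]_ref (with the µM→nM factor folded in);
        the reference pair is then reproduced exactly by steady_state_no.
        """
        if d_ref_um <= 0 or no_ref_nm <= 0:
            raise ValueError("reference pair must be > 0")
        self.k_c_per_h = self.no_yield * self.decay_rate_per_h * d_ref_um * 1000.0 / no_ref_nm
        return self.k_c_per_h

    def steady_state_no(self) -> float:
        """Quasi-steady NO concentration ν·k_d·D0/k_c, in nM; linear in D0."""
        if self.k_c_per_h is None or self.k_c_per_h <= 0:
            raise ValueError("k_c must be calibrated (see calibrate_kc)")
        return self.no_yield * self.decay_rate_per_h * self.d0_um * 1000.0 / self.k_c_per_h
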