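"""Shared parameter containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class BisseParams:
    """The six BiSSE rates, all in events·lineage⁻¹·Myr⁻¹.

    States: O (0, outcrossing/ancestral) and S (1, selfing/derived).
    ``q_os`` is the O→S transition rate, ``q_so`` the reverse.
    """

    lam_o: float
    lam_s: float
    mu_o: float
    mu_s: float
    q_os: float
    q_so: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"BiSSE rate {name} must be >= 0, got {v}")

    @property
    def r_o(self) -> float:
        """Net diversification of outcrossers, λ_O − μ_O."""
        return self.lam_o - self.mu_o

    @property
    def r_s(self) -> float:
        """Net diversification of selfers, λ_S − μ_S."""
        return self.lam_s - self.mu_s

    def as_array(self) -> np.ndarray:
        return np.array([self.lam_o, self.lam_s, self.mu_o, self.mu_s,
                         self.q_os, self.q_so], dtype=float)

    def as_dict(self) -> dict:
        return {"lam_o": self.lam_o, "lam_s": self.lam_s, "mu_o": self.mu_o,
                "mu_s": self.mu_s, "q_os": self.q_os, "q_so": self.q_so}

    @classmethod
    def from_array(cls, a) -> "BisseParams":
        return cls(*[float(x) for x in a])


PARAM_NAMES = ("lam_o", "lam_s", "mu_o", "mu_s", "q_os", "q_so")
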