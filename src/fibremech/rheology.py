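"""Creep–recovery and live-cell rheology analysis.

Two measurements are covered:

* **Degree of plasticity** from a creep–recovery test: a constant shear
  stress is applied (creep), then released (recovery), and the fraction of
  strain that never recovers measures how plastically the network deformed.
* **Stiffening decomposition** from a live-cell storage-modulus time trace:
  cells contracting in the gel raise G′ over hours; abolishing contraction
  (cytochalasin D) removes the reversible, stress-induced part of the
  stiffening, while the plastic remodeling of the network persists as an
  irreversible offset over the cell-free baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CreepTrace",
    "ModulusTrace",
    "degree_of_plasticity",
    "decompose_stiffening",
]


@dataclass
class CreepTrace:
    """Strain response to a constant-stress creep phase followed by recovery.

    ``phase`` labels every sample ``"creep"`` or ``"recovery"``; there must be
    exactly one creep→recovery transition and time must strictly increase.
    """

    time_s: np.ndarray
    strain: np.ndarray
    phase: np.ndarray
    applied_stress_Pa: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time_s) == len(self.strain) == len(self.phase)):
            raise ValueError("time, strain and phase must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        is_rec = np.asarray([p == "recovery" for p in self.phase])
        transitions = np.flatnonzero(np.diff(is_rec.astype(int)) != 0)
        if len(transitions) != 1 or not is_rec[-1] or is_rec[0]:
            raise ValueError("trace must contain exactly one creep→recovery transition")

    @property
    def creep(self) -> np.ndarray:
        return np.asarray([p == "creep" for p in self.phase])

    @property
    def recovery(self) -> np.ndarray:
        return np.asarray([p == "recovery" for p in self.phase])


@dataclass
class ModulusTrace:
    """Storage modulus G′(t) of a cell–gel construct with a cytoD event.

    ``G_baseline_Pa`` is the modulus of the same gel without cells, the
    reference against which irreversible stiffening is measured.
    """

    time_h: np.ndarray
    G_prime_Pa: np.ndarray
    cytod_time_h: float
    G_baseline_Pa: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.G_prime_Pa = np.asarray(self.G_prime_Pa, dtype=float)
        if len(self.time_h) != len(self.G_prime_Pa):
            raise ValueError("time and G' must have equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.G_prime_Pa <= 0):
            raise ValueError("G' must be positive")
        if not (self.time_h[0] <= self.cytod_time_h <= self.time_h[-1]):
            raise ValueError(
                f"cytod_time_h={self.cytod_time_h} outside trace span "
                f"[{self.time_h[0]}, {self.time_h[-1]}]"
            )


def degree_of_plasticity(trace: CreepTrace, tail_fraction: float = 0.1) -> float:
    """Irreversible strain fraction after a creep–recovery test.

    The degree of plasticity is the ratio of the residual (irreversible)
    strain after recovery to the maximum strain at the end of the creep
    phase.  The residual is estimated as the mean strain over the final
    ``tail_fraction`` of the recovery phase, which is robust to instrument
    noise; a warning is issued if the tail has not equilibrated (relative
    slope above 1 %/min).

    Returns the ratio clipped to [0, 1] (with a warning if clipping occurred).
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    eps_max = float(trace.strain[trace.creep][-1])
    if eps_max <= 0:
        raise ValueError(f"maximum creep strain must be positive, got {eps_max}")

    rec_t = trace.time_s[trace.recovery]
    rec_eps = trace.strain[trace.recovery]
    n_tail = max(1, int(round(tail_fraction * len(rec_eps))))
    tail_t, tail_eps = rec_t[-n_tail:], rec_eps[-n_tail:]

    if n_tail >= 2:
        slope_per_s = np.polyfit(tail_t, tail_eps, 1)[0]
        mean_tail = float(np.mean(np.abs(tail_eps)))
        if mean_tail > 0 and abs(slope_per_s) * 60.0 / mean_tail > 0.01:
            warnings.warn(
                "recovery tail not equilibrated (relative slope > 1%/min); "
                "degree of plasticity may be overestimated",
                stacklevel=2,
            )
    ratio = float(np.mean(tail_eps)) / eps_max
    if not 0.0 <= ratio <= 1.0:
        warnings.warn(
            f"degree of plasticity {ratio:.3g} outside [0, 1]; clipping", stacklevel=2
        )
        ratio = float(np.clip(ratio, 0.0, 1.0))
    return ratio


def decompose_stiffening(
    trace: ModulusTrace, window_h: float = 1.0
) -> tuple[float, float | None, float | None]:
    """Split cell-induced stiffening into reversible and irreversible parts.

    * ``reversible_Pa`` — drop in G′ caused by abolishing contraction:
      mean G′ over the ``window_h`` hours before the cytoD event minus the
      mean over the final ``window_h`` hours of the trace.
    * ``irreversible_Pa`` — residual stiffening over the cell-free gel:
      post-cytoD level minus ``G_baseline_Pa`` (None if no baseline).
    * ``stiffening_ratio`` — pre-cytoD plateau over baseline (None if no
      baseline).

    Returns ``(reversible_Pa, irreversible_Pa, stiffening_ratio)``.
    """
    t, g = trace.time_h, trace.G_prime_Pa
    pre = (t >= trace.cytod_time_h - window_h) & (t < trace.cytod_time_h)
    post = t >= t[-1] - window_h
    if not pre.any():
        raise ValueError("no samples in the pre-cytoD plateau window")
    g_plateau = float(np.mean(g[pre]))
    g_post = float(np.mean(g[post]))
    reversible = g_plateau - g_post
    if trace.G_baseline_Pa is None:
        warnings.warn(
            "no cell-free baseline: irreversible stiffening and ratio undefined",
            stacklevel=2,
        )
        return reversible, None, None
    irreversible = g_post - trace.G_baseline_Pa
    ratio = g_plateau / trace.G_baseline_Pa
    return reversible, irreversible, ratio
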