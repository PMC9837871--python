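"""Stimulation/measurement electrode combinations.

A protocol is an ordered list of four-electrode combinations
``(stim_pos, stim_neg, meas_pos, meas_neg)`` (1-based electrode numbers).
Current is driven between the stimulation pair while the voltage is read
between the measurement pair; pairs never share an electrode.

The quasi-adjacent pattern drives and measures across pairs separated by one
electrode (span 2), which raises the measured voltages relative to the
strictly adjacent pattern (span 1) and therefore the SNR.  With 16
electrodes either span gives 16 loops of 13 measurements = 208 combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Protocol", "build_protocol", "save_protocol", "load_protocol"]


@dataclass(frozen=True)
class Protocol:
    combinations: np.ndarray  # (M, 4) int, 1-based electrode numbers
    n_electrodes: int
    stim_span: int
    meas_span: int

    def __len__(self) -> int:
        return len(self.combinations)

    @property
    def n_per_loop(self) -> int:
        return len(self.combinations) // self.n_electrodes

    def stim_pairs(self) -> np.ndarray:
        """Distinct stimulation pairs in loop order, shape (L, 2)."""
        return self.combinations[:: self.n_per_loop, :2]

    def reciprocal_pairs(self) -> list:
        """Index pairs (i, j), i < j, of mutually reciprocal combinations.

        Combination j is the reciprocal of i when its stimulation pair equals
        i's measurement pair and vice versa.
        """
        index = {tuple(c): k for k, c in enumerate(map(tuple, self.combinations))}
        out = []
        for i, (sp, sn, mp, mn) in enumerate(self.combinations):
            j = index.get((mp, mn, sp, sn))
            if j is not None and i < j:
                out.append((i, j))
        return out


def build_protocol(n_electrodes: int, stim_span: int = 2, meas_span: int = 2) -> Protocol:
    """Enumerate the stimulation/measurement combinations.

    One loop per stimulation position ``l = 1..L`` with stimulation pair
    ``(l, l+stim_span)`` (indices mod L); within a loop, all measurement
    pairs ``(m, m+meas_span)`` that do not touch a stimulation electrode, in
    ascending ``m``.  ``stim_span = meas_span = 2`` is the quasi-adjacent
    pattern, ``1`` the adjacent pattern.
    """
    L = n_electrodes
    for name, span in (("stim_span", stim_span), ("meas_span", meas_span)):
        if not 1 <= span < L / 2:
            raise ValueError(f"{name} must satisfy 1 <= span < L/2")
    wrap = lambda e: (e - 1) % L + 1
    combos = []
    for l in range(1, L + 1):
        sp, sn = l, wrap(l + stim_span)
        for m in range(1, L + 1):
            mp, mn = m, wrap(m + meas_span)
            if {mp, mn} & {sp, sn}:
                continue
            combos.append((sp, sn, mp, mn))
    return Protocol(np.array(combos, dtype=int), L, stim_span, meas_span)


def save_protocol(protocol: Protocol, path) -> None:
    pd.DataFrame(
        protocol.combinations,
        columns=["stim_pos", "stim_neg", "meas_pos", "meas_neg"],
    ).to_csv(path, index=False)


def load_protocol(path, n_electrodes: int, stim_span: int = 2,
                  meas_span: int = 2) -> Protocol:
    df = pd.read_csv(path)
    combos = df[["stim_pos", "stim_neg", "meas_pos", "meas_neg"]].to_numpy(int)
    return Protocol(combos, n_electrodes, stim_span, meas_span)
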