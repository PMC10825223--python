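"""Generative enzyme models for RNA base editors.

An :class:`EnzymeModel` describes one editor: which substitution it writes
(C-to-U read out as C>T, A-to-I read out as A>G, or both), how strongly it
edits near a tethered binding site (``peak_rate`` with a distance-decay
kernel), how much it edits untethered RNA (``background_rate``), and its
intrinsic flanking-base preference (``context_weights`` over the 16
upstream/downstream base pairs).  The context preference multiplies both the
recruited and the background editing rate: it is a property of the catalytic
domain, not of recruitment, which is why free (unfused) editors still leave
a recognizable sequence signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

BASES = "ACGT"
CONTEXTS: tuple[tuple[str, str], ...] = tuple(product(BASES, BASES))

C2U = "C2U"
A2I = "A2I"
DUAL = "DUAL"
EDIT_TYPES = (C2U, A2I, DUAL)

#: substrate and product base per channel, sense strand
CHANNEL_BASES = {C2U: ("C", "T"), A2I: ("A", "G")}


def uniform_weights() -> dict[tuple[str, str], float]:
    return {c: 1.0 for c in CONTEXTS}


def _flank_weights(favored: str, ratio: float) -> dict[tuple[str, str], float]:
    lo = ratio ** -0.5
    f = {b: (1.0 if b in favored else lo) for b in BASES}
    return {(u, d): f[u] * f[d] for (u, d) in CONTEXTS}


def au_rich_weights(ratio: float = 10.0) -> dict[tuple[str, str], float]:
    """Favor A/U(T) flanks over G/C by ``ratio`` when both flanks are favored."""
    return _flank_weights("AT", ratio)


def gc_rich_weights(ratio: float = 10.0) -> dict[tuple[str, str], float]:
    """Favor G/C flanks over A/U(T) by ``ratio`` when both flanks are favored."""
    return _flank_weights("GC", ratio)


def _check_rate(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {x}")


@dataclass(frozen=True)
class EnzymeModel:
    """One RNA base editor.

    For ``edit_type == DUAL`` the primary ``peak_rate``/``background_rate``/
    ``context_weights`` describe the C-to-U channel and the ``a2i_*`` fields
    the independent A-to-I channel.  ``kernel_halfwidth`` (bp) sets the scale
    of the distance decay around a bound site; ``kernel_shape`` is
    ``"gaussian"`` (exp(-d^2/2h^2), truncated at 4h) or ``"flat"``
    (1 inside +-h, 0 outside).
    """

    name: str
    edit_type: str
    peak_rate: float
    kernel_halfwidth: float
    background_rate: float = 0.0
    context_weights: dict[tuple[str, str], float] = field(
        default_factory=uniform_weights
    )
    kernel_shape: str = "gaussian"
    a2i_peak_rate: float | None = None
    a2i_background_rate: float | None = None
    a2i_context_weights: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.edit_type not in EDIT_TYPES:
            raise ValueError(f"edit_type must be one of {EDIT_TYPES}")
        _check_rate(self.peak_rate, "peak_rate")
        _check_rate(self.background_rate, "background_rate")
        for w in self.context_weights.values():
            _check_rate(w, "context weight")
        if self.kernel_shape not in ("gaussian", "flat"):
            raise ValueError("kernel_shape must be 'gaussian' or 'flat'")
        if self.edit_type == DUAL:
            if self.a2i_peak_rate is None:
                raise ValueError("DUAL enzymes need a2i_peak_rate")
            _check_rate(self.a2i_peak_rate, "a2i_peak_rate")
            if self.a2i_background_rate is not None:
                _check_rate(self.a2i_background_rate, "a2i_background_rate")

    def channels(self) -> list[tuple[str, float, float, dict[tuple[str, str], float]]]:
        """(channel, peak_rate, background_rate, context_weights) per channel."""
        if self.edit_type == DUAL:
            return [
                (C2U, self.peak_rate, self.background_rate, self.context_weights),
                (
                    A2I,
                    float(self.a2i_peak_rate),
                    self.a2i_background_rate
                    if self.a2i_background_rate is not None
                    else self.background_rate,
                    self.a2i_context_weights or self.context_weights,
                ),
            ]
        return [
            (
                self.edit_type,
                self.peak_rate,
                self.background_rate,
                self.context_weights,
            )
        ]

    def kernel(self, dist: np.ndarray) -> np.ndarray:
        """Distance-decay factor in [0, 1] for distances in bp."""
        d = np.asarray(dist, dtype=float)
        h = self.kernel_halfwidth
        if self.kernel_shape == "flat":
            return (d <= h).astype(float)
        k = np.exp(-0.5 * (d / h) ** 2)
        k[d > 4.0 * h] = 0.0
        return k


def weight_matrix(weights: dict[tuple[str, str], float]) -> np.ndarray:
    """4x4 matrix W[up, down] in A,C,G,T encoding order."""
    w = np.ones((4, 4))
    for (u, d), v in weights.items():
        w[BASES.index(u), BASES.index(d)] = v
    return w
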