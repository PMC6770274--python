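"""Fragment-length models for simulated cfDNA.

Two families cover the shapes seen in plasma sequencing:

* ``nucleosomal_ladder`` — nuclear cfDNA: a dominant Gaussian at the
  mono-nucleosome modal length (tumor ~144 bp, normal ~169 bp) plus,
  with probability ``ladder_weight``, a comb of equally weighted
  Gaussians at ``modal_length - k * ladder_period`` (k >= 1, stopping at
  ``ladder_min``).  The ~10.6 bp comb spacing reproduces the
  sub-nucleosomal ladder of the 50-150 bp region.
* ``gamma`` — mitochondrial cfDNA, which lacks nucleosomal structure:
  a gamma with a given mean and shape (tumor-derived mt-cfDNA is
  shorter, mean ~109 bp, vs host ~143 bp).

Draws are integers restricted to [30, 1000] bp by resampling, emulating
the under-representation of very short and very long fragments in real
libraries without modelling the bias explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

LADDER = "nucleosomal_ladder"
GAMMA = "gamma"

#: retained fragment-length window, bp
MIN_LENGTH = 30
MAX_LENGTH = 1000


@dataclass(frozen=True)
class FragmentLengthModel:
    """Parametric fragment-length distribution (see module docstring).

    Ladder parameters are used when ``kind == "nucleosomal_ladder"``;
    ``mean_length``/``shape`` when ``kind == "gamma"``.
    """

    kind: str
    modal_length: float | None = None
    modal_sd: float = 3.0
    ladder_period: float = 10.6
    ladder_min: float = 50.0
    ladder_weight: float = 0.3
    mean_length: float | None = None
    shape: float = 8.0

    def __post_init__(self):
        if self.kind not in (LADDER, GAMMA):
            raise ConfigError(f"unknown fragment length model kind {self.kind!r}")
        if self.kind == LADDER:
            if self.modal_length is None:
                raise ConfigError("nucleosomal_ladder model needs modal_length")
            if self.ladder_period <= 0:
                raise ConfigError("ladder_period must be > 0")
            if not 0.0 <= self.ladder_weight <= 1.0:
                raise ConfigError("ladder_weight must be in [0, 1]")
            if self.modal_sd <= 0:
                raise ConfigError("modal_sd must be > 0")
        else:
            if self.mean_length is None or self.mean_length <= 0:
                raise ConfigError("gamma model needs mean_length > 0")
            if self.shape <= 0:
                raise ConfigError("gamma shape must be > 0")

    def ladder_teeth(self) -> np.ndarray:
        """Comb centres ``modal - k*period`` for k >= 1, down to ladder_min."""
        if self.kind != LADDER:
            return np.empty(0)
        k_max = int(np.floor((self.modal_length - self.ladder_min) / self.ladder_period))
        return self.modal_length - self.ladder_period * np.arange(1, k_max + 1)


def draw_fragment_lengths(model: FragmentLengthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` integer fragment lengths in [30, 1000] bp.

    Out-of-window draws are resampled, so the returned array always has
    exactly ``n`` entries.  ``n == 0`` returns an empty array.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        need = n - filled
        raw = _draw_raw(model, need, rng)
        vals = np.rint(raw).astype(np.int64)
        ok = vals[(vals >= MIN_LENGTH) & (vals <= MAX_LENGTH)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return out


def _draw_raw(model: FragmentLengthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.kind == GAMMA:
        scale = model.mean_length / model.shape
        return rng.gamma(model.shape, scale, size=n)
    teeth = model.ladder_teeth()
    centers = np.full(n, float(model.modal_length))
    if teeth.size:
        in_ladder = rng.random(n) < model.ladder_weight
        k = rng.integers(0, teeth.size, size=n)
        centers[in_ladder] = teeth[k[in_ladder]]
    return rng.normal(centers, model.modal_sd)
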