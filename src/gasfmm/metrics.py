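"""Force accuracy metric: average relative difference over all 3N components.

The error of an approximate force field against the direct oracle is an
average relative difference over every per-atom Cartesian force component
(one per atom and spatial direction), reported in percent.  The default
normalization divides the mean absolute component deviation by the mean
absolute reference component,

    delta = sum_chi |f_hat_chi - f_chi| / sum_chi |f_chi|,

which is stable against the components whose reference value happens to
cross zero and reproduces the round-off-scale discrepancies between
independent explicit-summation codes that motivate the 0.016% accuracy
budget.  Two variants are available: ``"component"`` averages the
per-component ratios |f_hat - f| / |f| directly (components below a
relative denominator floor are excluded and counted), and ``"rms"``
normalizes by the RMS component magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .direct import ForceResult

#: relative denominator floor for the per-component variant: components
#: with |f| below this fraction of the RMS component magnitude are
#: excluded from the mean (the ratio is numerically meaningless there)
DENOMINATOR_FLOOR = 1e-6


@dataclass
class ErrorReport:
    """Average relative force-component error of an approximate method."""

    delta_percent: float
    n_components: int
    n_excluded: int
    per_particle_worst: float
    normalization: str
    floor: float
    approx_provenance: str

    def to_dict(self) -> dict:
        return asdict(self)


def force_error(reference: ForceResult, approx: ForceResult,
                floor: float = DENOMINATOR_FLOOR,
                normalization: str = "mean_abs") -> ErrorReport:
    """Compare an approximate force table against the direct reference.

    Parameters
    ----------
    reference, approx :
        Force results over the same particles; the reference should come
        from exact summation.
    floor :
        Relative denominator floor for the ``"component"`` variant.
    normalization :
        ``"mean_abs"`` (default), ``"component"`` or ``"rms"``; see the
        module docstring.

    Returns
    -------
    ErrorReport with the error in percent; ``per_particle_worst`` is the
    largest single-component relative deviation (against the same
    denominator the chosen normalization uses).
    """
    f = np.asarray(reference.forces, dtype=float).ravel()
    fh = np.asarray(approx.forces, dtype=float).ravel()
    if f.shape != fh.shape:
        raise ValueError(
            f"force tables differ in size ({reference.n} vs {approx.n} particles)"
        )
    dev = np.abs(fh - f)
    mag = np.abs(f)
    rms = float(np.sqrt(np.mean(mag ** 2)))
    n_excluded = 0
    if normalization == "mean_abs":
        denom = float(mag.mean())
        if denom == 0.0:
            raise ValueError("all reference components are zero")
        delta = float(dev.mean()) / denom
        worst = float(dev.max()) / denom
    elif normalization == "rms":
        if rms == 0.0:
            raise ValueError("all reference components are zero")
        delta = float(dev.mean()) / rms
        worst = float(dev.max()) / rms
    elif normalization == "component":
        included = mag >= floor * rms
        if not np.any(included):
            raise ValueError("all components fall below the denominator floor")
        ratios = dev[included] / mag[included]
        delta = float(ratios.mean())
        worst = float(ratios.max())
        n_excluded = int(f.size - included.sum())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ErrorReport(
        delta_percent=100.0 * delta,
        n_components=int(f.size),
        n_excluded=n_excluded,
        per_particle_worst=worst,
        normalization=normalization,
        floor=floor,
        approx_provenance=approx.provenance,
    )


def plateau_onset(p_values, deltas, flat_ratio: float = 0.5) -> int:
    """Order p at which an error-vs-order curve levels off.

    Operationalizes the visual flattening of a log-scale error curve: the
    onset is the smallest p from which the error never again improves by a
    factor of ``1/flat_ratio`` in a single step (i.e. every subsequent
    per-step decay ratio exceeds ``flat_ratio``).
    """
    p_values = list(p_values)
    deltas = np.asarray(list(deltas), dtype=float)
    if len(p_values) != deltas.size or deltas.size < 2:
        raise ValueError("need matching p_values and deltas with >= 2 entries")
    ratios = deltas[1:] / np.maximum(deltas[:-1], 1e-300)
    onset = p_values[0]
    for i in range(ratios.size - 1, -1, -1):
        if ratios[i] <= flat_ratio:
            onset = p_values[i + 1]
            break
    return int(onset)
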