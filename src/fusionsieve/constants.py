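"""Model constants and filter thresholds.

The noise-model constants are empirically determined values of the
background-noise e-value model (trained on a large clinical RNA-seq
cohort); they are stable across data sets and are therefore shipped as
fixed defaults.  Every value can be overridden through a ``key=value``
config file (see :func:`load_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, TextIO


@dataclass(frozen=True)
class NoiseConstants:
    """Constants of the polynomial background-noise model.

    The e-value of a fusion candidate is the product of five factors:
    a per-gene base noise level, a sequencing-depth penalty, a
    breakpoint-distance penalty and two event-composition ratios.
    """

    #: horizontal shift of the polynomial decay in supporting reads
    shift_noise: float = -0.73
    #: exponent of the polynomial decay in supporting reads
    slope_noise: float = -2.28
    #: scale of the per-gene base noise level
    intercept_noise: float = 10 ** -1.75
    #: slope of the linear depth penalty (per mapped read)
    slope_depth: float = 2e-11
    #: per-supporting-read attenuation of the depth slope
    slope_modifier: float = 0.02
    #: distance-penalty exponent for breakpoints < 400 bp apart
    slope_distance_near: float = -4.58
    intercept_distance_near: float = 8.27e10
    #: distance-penalty exponent for breakpoints >= 400 bp apart
    slope_distance_far: float = -1.53
    intercept_distance_far: float = 3.73e8
    #: boundary between the near and far distance regimes (bp)
    distance_regime_boundary: int = 400
    #: distance above which no penalty is applied (bp)
    distance_penalty_ceiling: int = 400_000

    def __post_init__(self) -> None:
        if not self.distance_regime_boundary < self.distance_penalty_ceiling:
            raise ValueError(
                "distance_regime_boundary must be below distance_penalty_ceiling"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable thresholds of the artifact filters and rescues.

    Only ``sv_window`` (structural-variant corroboration distance) and
    the >= 4 distinct spliced breakpoints rule of the multi-transcript
    rescue are fixed by the method description; the remaining values are
    package defaults exposed for configuration.
    """

    #: minimum supporting reads to pass the noise filter (<= 2 reads is
    #: at/below the detection limit)
    min_support: int = 3
    #: minimum supporting reads for the splice-site rescue
    rescue_min: int = 2
    #: homopolymer run length near the junction flagged as artifact (bp)
    homopolymer_len: int = 6
    #: maximum repeat-unit size scanned for tandem repeats (bp)
    repeat_unit_max: int = 4
    #: minimum span of a tandem repeat flagged as artifact (bp)
    repeat_min_span: int = 12
    #: assumed per-base sequencing error rate
    mismatch_rate: float = 0.01
    #: significance level of the binomial mismatch-excess test
    mismatch_alpha: float = 0.01
    #: window around the junction scanned for sequence artifacts (bp)
    artifact_window: int = 30
    #: minimum anchor length on both sides of a split read (bp)
    min_anchor: int = 23
    #: k-mer size for the gene-homology screen
    homology_k: int = 16
    #: maximum tolerated shared-k-mer fraction between fusion partners
    max_identity: float = 0.3
    #: maximum breakpoint-to-SV distance for corroboration (bp)
    sv_window: int = 100_000
    #: window for attaching discordant mates to a split-read junction (bp)
    mate_window: int = 500
    #: distinct spliced breakpoints in one gene needed for the
    #: multi-transcript rescue
    multi_transcript_min: int = 4
    #: default tolerance of position-pair blacklist entries (bp)
    blacklist_tolerance: int = 100
    #: minimum reads for the high confidence class
    high_confidence_support: int = 4


def _coerce(value: str, target: Any) -> Any:
    if isinstance(target, bool):
        return value.strip().lower() in {"1", "true", "yes", "on"}
    if isinstance(target, int):
        return int(float(value))
    if isinstance(target, float):
        return float(value)
    return value


def load_config(
    stream: TextIO,
    constants: NoiseConstants | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[NoiseConstants, FilterThresholds]:
    """Read ``key=value`` overrides for constants and thresholds.

    Blank lines and ``#`` comments are ignored.  Unknown keys raise
    :class:`KeyError` so that typos never silently fall back to
    defaults.
    """
    constants = constants or NoiseConstants()
    thresholds = thresholds or FilterThresholds()
    const_names = {f.name for f in fields(NoiseConstants)}
    thr_names = {f.name for f in fields(FilterThresholds)}
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw.rstrip()!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in const_names:
            constants = replace(
                constants, **{key: _coerce(value, getattr(constants, key))}
            )
        elif key in thr_names:
            thresholds = replace(
                thresholds, **{key: _coerce(value, getattr(thresholds, key))}
            )
        else:
            raise KeyError(f"unknown config key: {key}")
    return constants, thresholds
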