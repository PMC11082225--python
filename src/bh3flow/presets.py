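"""Ground-truth presets for the synthetic flow-cytometry generator.

Each preset encodes the "truth" of one biological scenario from the
CLL / Richter's syndrome (RS) contrast: per-condition probabilities that a
target B cell releases cytochrome c when exposed to a BH3 peptide or BH3
mimetic, the subpopulation composition of a tube, and the channel
distributions.  Where a cohort mean or a sample-level response is printed in
the study this package models, the corresponding release probability equals
that value divided by 100; the remaining values are plausible fill-ins
documented in docs/methods.md.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .events import ValidationError

#: populations emitted by the generator
POPULATIONS = ("debris", "doublet", "dead", "non_target", "target")

ConditionKey = Tuple[str, float]


@dataclass
class FourPLTruth:
    """4PL ground truth for a titrated reagent (response on the % loss scale)."""

    bottom: float
    top: float
    log_ec50: float   # log10 of EC50 in uM
    hill: float

    def response(self, conc_uM):
        import numpy as np
        c = np.asarray(conc_uM, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (self.hill * (self.log_ec50 - np.log10(c)))
        )

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    def ec_fraction(self, f: float) -> float:
        """Closed-form concentration attaining absolute response ``f`` (%)."""
        f_rel = 100.0 * (f - self.bottom) / (self.top - self.bottom)
        return self.ec50 * (f_rel / (100.0 - f_rel)) ** (1.0 / self.hill)


@dataclass
class GeneratorPreset:
    """Complete, validated truth object for simulating one sample type.

    ``release_prob`` maps ``(reagent, concentration_uM)`` to the probability
    that a *target* cell releases cyt c under that condition.  The cyt-c
    channel of every cell is a two-component mixture: retained cells draw
    from a high-intensity component, released cells from a strictly lower
    one.  Both components are broad truncated normals with equal spread so
    that the population median responds smoothly to the released fraction,
    emulating the graded per-cell release seen in permeabilized cells.
    """

    name: str
    release_prob: Dict[ConditionKey, float]
    subpop_fracs: Dict[str, float]
    mfi_retained: Tuple[float, float]   # (location, scale) of retained cyt-c
    mfi_released: Tuple[float, float]   # (location, scale) of released cyt-c
    scatter_params: Dict[str, Dict[str, Tuple[float, float]]]
    marker_params: Dict[str, Dict[str, Tuple[float, float]]]
    dose_response_truth: Optional[Dict[str, FourPLTruth]] = None
    dead_release_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key, p in self.release_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"release_prob[{key}] = {p} outside [0, 1]"
                )
        if set(self.subpop_fracs) != set(POPULATIONS):
            raise ValidationError(
                f"subpop_fracs must cover exactly {POPULATIONS}"
            )
        for pop, frac in self.subpop_fracs.items():
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(
                    f"subpop_fracs.{pop} = {frac} outside [0, 1]"
                )
        total = sum(self.subpop_fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"subpop_fracs sums to {total}, expected 1"
            )
        if not self.mfi_released[0] < self.mfi_retained[0]:
            raise ValidationError(
                "mfi_released location must be strictly below mfi_retained"
            )
        if not (0.0 <= self.dead_release_prob <= 1.0):
            raise ValidationError("dead_release_prob outside [0, 1]")

    def release_probability(self, reagent: str, concentration_uM: float) -> float:
        key = (reagent, float(concentration_uM))
        if key not in self.release_prob:
            raise KeyError(
                f"preset {self.name!r} has no release probability for "
                f"{reagent} at {concentration_uM} uM"
            )
        return self.release_prob[key]

    def conditions(self):
        return sorted(self.release_prob)


# ---------------------------------------------------------------------------
# Shared channel models
# ---------------------------------------------------------------------------

def _default_scatter() -> Dict[str, Dict[str, Tuple[float, float]]]:
    # log-normal (median, log-sd) per population; doublets are built from two
    # singlet draws at simulation time, so their entry mirrors the target one.
    return {
        "target":     {"FSC-A": (52000.0, 0.12), "SSC-A": (21000.0, 0.18)},
        "dead":       {"FSC-A": (45000.0, 0.15), "SSC-A": (24000.0, 0.20)},
        "non_target": {"FSC-A": (50000.0, 0.13), "SSC-A": (20000.0, 0.18)},
        "doublet":    {"FSC-A": (52000.0, 0.12), "SSC-A": (21000.0, 0.18)},
        "debris":     {"FSC-A": (6000.0, 0.45),  "SSC-A": (2500.0, 0.50)},
    }


def _default_markers() -> Dict[str, Dict[str, Tuple[float, float]]]:
    # (median, log-sd) of log-normal marker/viability intensities
    return {
        "target":     {"Zombie": (300.0, 0.35), "CD5": (9000.0, 0.30), "CD19": (9000.0, 0.30)},
        "dead":       {"Zombie": (3000.0, 0.30), "CD5": (9000.0, 0.30), "CD19": (9000.0, 0.30)},
        "non_target": {"Zombie": (300.0, 0.35), "CD5": (9000.0, 0.30), "CD19": (250.0, 0.40)},
        "doublet":    {"Zombie": (300.0, 0.35), "CD5": (9000.0, 0.30), "CD19": (9000.0, 0.30)},
        "debris":     {"Zombie": (200.0, 0.50), "CD5": (150.0, 0.60), "CD19": (150.0, 0.60)},
    }


#: default subpopulation mix of a simulated tube
DEFAULT_SUBPOP_FRACS = {
    "debris": 0.05, "doublet": 0.05, "dead": 0.07,
    "non_target": 0.20, "target": 0.63,
}

#: cyt-c mixture components (location, scale); broad and overlapping on
#: purpose — see docs/methods.md on median linearity
MFI_RETAINED = (4000.0, 1400.0)
MFI_RELEASED = (3100.0, 1400.0)


def _p(**kw) -> Dict[ConditionKey, float]:
    """Helper: build a release_prob map from reagent=(conc, prob) pairs."""
    out = {}
    for reagent, entries in kw.items():
        name = reagent.replace("_", "-")
        for conc, prob in entries:
            out[(name, float(conc))] = prob
    return out


# ---------------------------------------------------------------------------
# Named presets
#
# Values on the 0-1 scale; entries marked "printed" equal a percentage
# printed for the cohort/sample divided by 100.  All others are plausible
# fill-ins consistent with the qualitative description of each sample.
# ---------------------------------------------------------------------------

def _build_presets() -> Dict[str, dict]:
    common = dict(
        subpop_fracs=dict(DEFAULT_SUBPOP_FRACS),
        mfi_retained=MFI_RETAINED,
        mfi_released=MFI_RELEASED,
        scatter_params=_default_scatter(),
        marker_params=_default_markers(),
    )

    presets: Dict[str, dict] = {}

    # CLL cohort composite: highly primed, strongly BCL-2 dependent.
    presets["CLL"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.972)],      # printed cohort mean
            BID=[(10.0, 0.970)],      # printed
            PUMA=[(10.0, 0.975)],     # printed
            BMF=[(10.0, 0.964)],      # printed
            BAD=[(10.0, 0.900)],      # fill-in; BAD - HRK = 0.728 printed
            HRK=[(10.0, 0.172)],      # fill-in complement of the printed difference
            MS_1=[(10.0, 0.100)],
            FS_1=[(10.0, 0.080)],
            venetoclax=[(0.1, 0.850)],
        ),
        dose_response_truth={
            # EC90 = 0.08 uM printed for the CLL cohort; hill 1, full range
            "BIM": FourPLTruth(bottom=0.0, top=100.0,
                               log_ec50=math.log10(0.08 / 9.0), hill=1.0),
        },
    )

    # RS cohort composite: reduced priming, loss of BCL-2 dependence.
    presets["RS"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.714)],      # printed cohort mean
            BID=[(10.0, 0.603)],      # printed
            PUMA=[(10.0, 0.671)],     # printed
            BMF=[(10.0, 0.725)],      # printed
            BAD=[(10.0, 0.350)],      # fill-in; BAD - HRK = 0.188 printed
            HRK=[(10.0, 0.162)],
            MS_1=[(10.0, 0.200)],
            FS_1=[(10.0, 0.120)],
            venetoclax=[(0.1, 0.250)],
        ),
    )

    # RS with no detectable BCL-2 protein; co-dependent on MCL-1/BCL-xL/BFL-1;
    # the only model responding to the BCL-xL antagonist A-1331852.
    presets["RS1050"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.700)],
            PUMA=[(10.0, 0.650)],
            BAD=[(10.0, 0.480)],
            HRK=[(10.0, 0.450)],
            MS_1=[(10.0, 0.500)],
            FS_1=[(10.0, 0.400)],
            A_1331852=[(0.1, 0.423)],  # printed sample-level response
            venetoclax=[(0.1, 0.100)],
        ),
    )

    # Generic RS retaining expression but little functional BCL-2 dependence.
    presets["RS_BCL2LOW"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.650)],
            PUMA=[(10.0, 0.600)],
            BAD=[(10.0, 0.220)],
            HRK=[(10.0, 0.180)],
            MS_1=[(10.0, 0.150)],
            FS_1=[(10.0, 0.120)],
        ),
    )

    # RS-PDX, mainly MCL-1 dependent at the 10 uM panel; the 1 uM entries are
    # the untreated (DMSO) baseline of the extended dynamic profiling assay.
    presets["RS1316"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.700)],
            PUMA=[(10.0, 0.640)],
            BAD=[(10.0, 0.300), (1.0, 0.250)],
            HRK=[(10.0, 0.120), (1.0, 0.100)],
            MS_1=[(10.0, 0.550), (1.0, 0.120)],
            FS_1=[(10.0, 0.100), (1.0, 0.080)],
        ),
    )

    # RS1316 after 6 h of 1 uM copanlisib: dependencies raised by the printed
    # deltas (+38 MCL-1, +47 BCL-xL, +40 BFL-1) over the 1 uM baseline.
    presets["RS1316_copanlisib_6h"] = dict(
        common,
        release_prob=_p(
            BAD=[(1.0, 0.300)],
            HRK=[(1.0, 0.570)],   # baseline 0.10 + printed delta 0.47
            MS_1=[(1.0, 0.500)],  # baseline 0.12 + printed delta 0.38
            FS_1=[(1.0, 0.480)],  # baseline 0.08 + printed delta 0.40
        ),
    )

    # RSVR3 before ibrutinib: highest priming among RS, strong MCL-1
    # dependence (printed 90.8%), EC90 for BIM reached at 0.73 uM (printed).
    presets["RSVR3_pre"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.900)],
            BAD=[(10.0, 0.400)],
            HRK=[(10.0, 0.150)],
            MS_1=[(10.0, 0.908)],     # printed
            FS_1=[(10.0, 0.100)],
            venetoclax=[(0.1, 0.200)],
        ),
        dose_response_truth={
            "BIM": FourPLTruth(bottom=0.0, top=100.0,
                               log_ec50=math.log10(0.73 / 9.0), hill=1.0),
        },
    )

    # RSVR3 two weeks into ibrutinib: MCL-1 dependency fell to 39.9%
    # (printed); priming stays high, transient BCL-2 dependence uptick.
    presets["RSVR3_ibrutinib"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.900)],
            BAD=[(10.0, 0.450)],
            HRK=[(10.0, 0.150)],
            MS_1=[(10.0, 0.399)],     # printed
            FS_1=[(10.0, 0.100)],
        ),
    )

    # RS with no clear anti-apoptotic dependency (U-RT1 / IP867-like), with
    # marked loss of PUMA-triggered priming.
    presets["RS_no_dependency"] = dict(
        common,
        release_prob=_p(
            BIM=[(10.0, 0.550)],
            PUMA=[(10.0, 0.350)],
            BAD=[(10.0, 0.150)],
            HRK=[(10.0, 0.120)],
            MS_1=[(10.0, 0.140)],
            FS_1=[(10.0, 0.100)],
        ),
    )

    return presets


_PRESETS = _build_presets()

PRESET_NAMES = tuple(sorted(_PRESETS))


def _apply_override(spec: dict, dotted_key: str, value) -> None:
    parts = dotted_key.split(".")
    node = spec
    for part in parts[:-1]:
        if part not in node:
            raise ValidationError(f"unknown preset field {dotted_key!r}")
        node = node[part]
    leaf = parts[-1]
    if leaf not in node and not isinstance(node, dict):
        raise ValidationError(f"unknown preset field {dotted_key!r}")
    node[leaf] = value


def make_preset(name: str, overrides: Optional[dict] = None, **kw_overrides) -> GeneratorPreset:
    """Return a fully populated, validated generator preset.

    Parameters
    ----------
    name
        One of :data:`PRESET_NAMES`.
    overrides
        Optional map of dotted field paths to replacement values, e.g.
        ``{"subpop_fracs.debris": 0.10}`` or ``{"release_prob": {...}}``.
        Keyword arguments are merged into ``overrides`` with ``__``
        standing in for the dot.

    Raises
    ------
    ValidationError
        For an unknown preset name or an override that violates a preset
        invariant (the error names the offending field).
    """
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; known presets: {', '.join(PRESET_NAMES)}"
        )
    spec = copy.deepcopy(_PRESETS[name])
    merged = dict(overrides or {})
    for key, val in kw_overrides.items():
        merged[key.replace("__", ".")] = val
    for dotted, value in merged.items():
        _apply_override(spec, dotted, value)
    return GeneratorPreset(name=name, **spec)
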