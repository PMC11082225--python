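"""Priming metrics: % cyt c loss, anti-apoptotic dependencies, delta priming.

Normalization contract
----------------------
Each tube's median cyt-c intensity (MFI) is referenced to the two per-sample
controls: the inert PUMA2A peptide defines full retention (0% loss) and
25 uM alamethicin defines complete release (100% loss).  The default
orientation is

    % cyt c loss = 100 * (MFI_PUMA2A - MFI_sample) / (MFI_PUMA2A - MFI_alamethicin)

so a sample matching the retention control scores 0 and one matching the
release control scores 100.  The commonly printed ratio
``(MFI_sample - MFI_alam) / (MFI_PUMA2A - MFI_alam)`` equals the *retained*
fraction under these control semantics; ``as_printed=True`` returns that
literal ratio x 100 instead (loss = 100 - printed value).

Dependency metrics follow the selective-peptide logic: BAD antagonizes
BCL-2 and BCL-xL while HRK is BCL-xL-specific, so BCL-2 dependence is the
BAD response minus the HRK response; MCL-1, BCL-xL and BFL-1 dependencies
are the MS-1, HRK and FS-1 responses respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .events import TubeRecord, ValidationError
from .gating import GatingResult

__all__ = [
    "LossValue", "PrimingProfile", "DependencyPanel", "DeltaPrimingResult",
    "cytc_loss", "build_profile", "dependency_metrics", "delta_priming",
    "extended_dbp", "call_dependencies", "DEPENDENCY_REAGENTS",
    "BASAL_WINDOW",
]

#: reagent probing each anti-apoptotic protein at the panel concentration
DEPENDENCY_REAGENTS = {"mcl1": "MS-1", "bclxl": "HRK", "bfl1": "FS-1"}

#: acceptable basal (vehicle) probe-induced release window for dynamic
#: profiling, in percent
BASAL_WINDOW = (10.0, 30.0)


class LossValue(float):
    """A % cyt c loss value; floats outside [0, 100] carry ``out_of_range``."""

    def __new__(cls, value: float):
        obj = super().__new__(cls, value)
        return obj

    @property
    def out_of_range(self) -> bool:
        return not (0.0 <= float(self) <= 100.0)


def cytc_loss(mfi_sample: float, mfi_alam: float, mfi_puma2a: float,
              as_printed: bool = False) -> LossValue:
    """Normalize a tube MFI to % cyt c loss between the two controls.

    Parameters
    ----------
    mfi_sample, mfi_alam, mfi_puma2a
        Median cyt-c intensities of the experimental tube, the alamethicin
        (complete release) control and the PUMA2A (full retention) control.
    as_printed
        Return the literal ratio
        ``100 * (MFI_sample - MFI_alam) / (MFI_PUMA2A - MFI_alam)`` —
        i.e. the retained fraction — instead of the loss.

    Raw values outside [0, 100] are returned as-is; the result's
    ``out_of_range`` attribute flags them.
    """
    if mfi_puma2a == mfi_alam:
        raise ValidationError(
            f"degenerate controls: MFI_PUMA2A == MFI_alamethicin == {mfi_alam}"
        )
    retained = 100.0 * (mfi_sample - mfi_alam) / (mfi_puma2a - mfi_alam)
    return LossValue(retained if as_printed else 100.0 - retained)


@dataclass
class PrimingProfile:
    """Per-sample map of conditions to % cyt c loss, with replicates kept."""

    sample_id: str
    losses: Dict[Tuple[str, float], float]
    replicate_losses: Dict[Tuple[str, float], List[float]]
    control_mfis: Tuple[float, float]          # (MFI_PUMA2A, MFI_alamethicin)
    qc: Dict[str, List[str]] = field(default_factory=dict)

    def loss(self, reagent: str, concentration_uM: Optional[float] = None) -> float:
        """Loss for a condition; the concentration may be omitted when the
        reagent appears at a single concentration."""
        if concentration_uM is not None:
            key = (reagent, float(concentration_uM))
            if key not in self.losses:
                raise KeyError(f"sample {self.sample_id!r}: no condition {key}")
            return self.losses[key]
        hits = [k for k in self.losses if k[0] == reagent]
        if not hits:
            raise KeyError(f"sample {self.sample_id!r}: reagent {reagent!r} absent")
        if len(hits) > 1:
            raise KeyError(
                f"sample {self.sample_id!r}: reagent {reagent!r} measured at "
                f"multiple concentrations {sorted(h[1] for h in hits)}; specify one"
            )
        return self.losses[hits[0]]

    def has(self, reagent: str, concentration_uM: Optional[float] = None) -> bool:
        try:
            self.loss(reagent, concentration_uM)
            return True
        except KeyError:
            return False


def build_profile(sample_tubes: Sequence[Tuple[TubeRecord, GatingResult]]) -> PrimingProfile:
    """Assemble a sample's priming profile from its gated tubes.

    Control MFIs are averaged across their replicate tubes; every
    experimental tube is normalized individually via :func:`cytc_loss` and
    replicate losses are then averaged per condition.  Replicate-level
    values are retained for dispersion reporting.
    """
    if not sample_tubes:
        raise ValidationError("no tubes supplied")
    sample_ids = {rec.sample_id for rec, _ in sample_tubes}
    if len(sample_ids) != 1:
        raise ValidationError(f"tubes span multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    control_mfis: Dict[str, List[float]] = {"PUMA2A": [], "alamethicin": []}
    experimental: Dict[Tuple[str, float], List[Tuple[TubeRecord, GatingResult]]] = {}
    qc: Dict[str, List[str]] = {}
    for rec, res in sample_tubes:
        if res.qc_flags:
            qc[f"{rec.reagent}@{rec.concentration_uM:g}uM/r{rec.replicate}"] = list(res.qc_flags)
        if rec.control_role in control_mfis:
            if res.mfi is not None:
                control_mfis[rec.control_role].append(res.mfi)
        else:
            experimental.setdefault(rec.condition, []).append((rec, res))

    for role, mfis in control_mfis.items():
        if not mfis:
            raise ValidationError(
                f"sample {sample_id!r} lacks a usable {role} control tube"
            )
    mfi_puma = float(np.mean(control_mfis["PUMA2A"]))
    mfi_alam = float(np.mean(control_mfis["alamethicin"]))

    losses: Dict[Tuple[str, float], float] = {}
    replicate_losses: Dict[Tuple[str, float], List[float]] = {}
    for cond, tubes in experimental.items():
        vals = [cytc_loss(res.mfi, mfi_alam, mfi_puma)
                for _, res in tubes if res.mfi is not None]
        if not vals:
            raise ValidationError(
                f"sample {sample_id!r}: condition {cond} has no valid tubes"
            )
        replicate_losses[cond] = [float(v) for v in vals]
        losses[cond] = float(np.mean(vals))
        if any(v.out_of_range for v in vals):
            qc.setdefault(f"{cond[0]}@{cond[1]:g}uM", []).append("out_of_range")
    return PrimingProfile(
        sample_id=sample_id, losses=losses, replicate_losses=replicate_losses,
        control_mfis=(mfi_puma, mfi_alam), qc=qc,
    )


@dataclass
class DependencyPanel:
    """Anti-apoptotic dependency metrics for one sample (percent).

    ``None`` marks a metric whose probing reagent was not measured —
    undefined, never zero.  Raw metrics are clamped into [-100, 100];
    a negative BCL-2 metric is kept raw and flagged.
    """

    sample_id: str
    bcl2_dep: Optional[float]
    mcl1_dep: Optional[float]
    bclxl_dep: Optional[float]
    bfl1_dep: Optional[float]
    venetoclax_response: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def metrics(self) -> Dict[str, Optional[float]]:
        return {
            "BCL-2": self.bcl2_dep, "MCL-1": self.mcl1_dep,
            "BCL-xL": self.bclxl_dep, "BFL-1": self.bfl1_dep,
        }


def _clamp_metric(value: float) -> float:
    return float(np.clip(value, -100.0, 100.0))


def dependency_metrics(
    profile: PrimingProfile,
    panel_concentration_uM: float = 10.0,
    venetoclax_concentration_uM: Optional[float] = None,
) -> DependencyPanel:
    """Derive the anti-apoptotic dependency panel from a priming profile.

    BCL-2 dependence is the BAD response minus the HRK response; MCL-1,
    BCL-xL and BFL-1 dependencies are the MS-1, HRK and FS-1 responses.
    A missing reagent leaves the corresponding metric undefined (None).
    """
    conc = float(panel_concentration_uM)
    flags: List[str] = []

    def get(reagent: str) -> Optional[float]:
        key = (reagent, conc)
        return profile.losses.get(key)

    bad, hrk = get("BAD"), get("HRK")
    bcl2 = None
    if bad is not None and hrk is not None:
        bcl2 = _clamp_metric(bad - hrk)
        if bcl2 < 0:
            flags.append("negative_bcl2_dep")
    mcl1 = get(DEPENDENCY_REAGENTS["mcl1"])
    bclxl = hrk
    bfl1 = get(DEPENDENCY_REAGENTS["bfl1"])

    ven = None
    if venetoclax_concentration_uM is not None:
        ven = profile.losses.get(("venetoclax", float(venetoclax_concentration_uM)))
    elif any(k[0] == "venetoclax" for k in profile.losses):
        ven = profile.loss("venetoclax")

    return DependencyPanel(
        sample_id=profile.sample_id,
        bcl2_dep=bcl2,
        mcl1_dep=_clamp_metric(mcl1) if mcl1 is not None else None,
        bclxl_dep=_clamp_metric(bclxl) if bclxl is not None else None,
        bfl1_dep=_clamp_metric(bfl1) if bfl1 is not None else None,
        venetoclax_response=ven,
        flags=flags,
    )


def call_dependencies(panel: DependencyPanel, threshold: float = 20.0) -> Dict[str, object]:
    """Dichotomize the panel: dependent iff metric >= threshold (percent).

    Returns a map protein -> bool (undefined metrics are skipped) plus the
    key ``"no_clear_dependency"`` set when nothing passes.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValidationError("threshold must lie in (0, 100]")
    calls: Dict[str, object] = {}
    any_dependent = False
    for protein, value in panel.metrics().items():
        if value is None:
            continue
        dependent = value >= threshold
        calls[protein] = dependent
        any_dependent |= dependent
    calls["no_clear_dependency"] = not any_dependent
    return calls


@dataclass
class DeltaPrimingResult:
    """Drug-induced change in priming for one probe condition."""

    drug: str
    delta: float          # loss(drug-treated) - loss(vehicle), percent
    basal_loss: float     # vehicle (DMSO) probe loss, percent
    qc: List[str] = field(default_factory=list)


def delta_priming(
    profile_drug: PrimingProfile,
    profile_dmso: PrimingProfile,
    reagent: str,
    concentration_uM: Optional[float] = None,
    drug: Optional[str] = None,
) -> DeltaPrimingResult:
    """Dynamic profiling readout: delta = loss_drug - loss_DMSO for a probe.

    The probe dose is chosen to give a basal (vehicle) release inside
    :data:`BASAL_WINDOW`; a vehicle loss outside [10, 30]% sets the
    ``basal_outside_window`` QC flag.
    """
    loss_drug = profile_drug.loss(reagent, concentration_uM)
    loss_dmso = profile_dmso.loss(reagent, concentration_uM)
    qc = []
    if not (BASAL_WINDOW[0] <= loss_dmso <= BASAL_WINDOW[1]):
        qc.append("basal_outside_window")
    return DeltaPrimingResult(
        drug=drug or profile_drug.sample_id,
        delta=float(loss_drug - loss_dmso),
        basal_loss=float(loss_dmso),
        qc=qc,
    )


def extended_dbp(
    treated: Union[PrimingProfile, Mapping[str, PrimingProfile]],
    untreated: PrimingProfile,
    panel_concentration_uM: float = 1.0,
) -> Dict[str, Optional[float]]:
    """Per-protein change in dependency metrics after a short drug exposure.

    ``treated`` is either one profile (returns protein -> delta) or a
    mapping of timepoint label -> profile (returns timepoint -> {protein ->
    delta}).  Both sides must be measured at the same panel concentration;
    a protein whose reagent is missing at either side is reported as None.
    """
    if isinstance(treated, Mapping):
        return {
            label: extended_dbp(prof, untreated, panel_concentration_uM)
            for label, prof in treated.items()
        }
    base = dependency_metrics(untreated, panel_concentration_uM)
    after = dependency_metrics(treated, panel_concentration_uM)
    deltas: Dict[str, Optional[float]] = {}
    for protein, b in base.metrics().items():
        a = after.metrics()[protein]
        deltas[protein] = None if (a is None or b is None) else float(a - b)
    return deltas
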