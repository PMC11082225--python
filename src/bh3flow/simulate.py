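"""Synthetic tube and cohort generation.

The generator emits raw cytometer events for one tube at a time: a mixture
of debris, doublets, dead cells, non-target cells and target cells.  Target
and non-target cells release cytochrome c with the preset's per-condition
probability; control roles override that probability (PUMA2A -> 0,
alamethicin -> 1); dead cells release with an elevated probability
regardless of condition.  Doublets are sums of two singlet scatter draws,
which places their FSC-H/FSC-A ratio below the singlet band.

Determinism: every tube derives its random stream from
``numpy.random.SeedSequence(master_seed, sample_index, tube_index)``, so the
same inputs always reproduce byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import DEFAULT_CHANNELS, EventTable, Manifest, TubeRecord, ValidationError
from .fcs import write_events_csv, write_fcs
from .presets import POPULATIONS, GeneratorPreset

__all__ = ["simulate_tube", "simulate_cohort", "resolve_release_prob"]


def resolve_release_prob(
    preset: GeneratorPreset,
    reagent: str,
    concentration_uM: float,
    control_role: str = "none",
) -> float:
    """Release probability for live target cells under a condition.

    Control roles take precedence over the preset's map: the inert PUMA2A
    peptide forces full retention (p = 0) and the pore-former alamethicin
    forces complete release (p = 1).  A DMSO vehicle tube is read from the
    preset like any other condition.
    """
    if control_role == "PUMA2A":
        return 0.0
    if control_role == "alamethicin":
        return 1.0
    return preset.release_probability(reagent, concentration_uM)


def _lognormal(rng: np.random.Generator, median: float, log_sd: float, n: int) -> np.ndarray:
    return rng.lognormal(mean=math.log(median), sigma=log_sd, size=n)


def _cytc_draw(rng: np.random.Generator, preset: GeneratorPreset,
               released: np.ndarray) -> np.ndarray:
    """Cyt-c intensities for cells given their released flags.

    Two broad equal-spread components truncated at zero; retained cells sit
    on the higher one.  Truncation clips the sub-zero tail to 0, which
    leaves the component medians untouched.
    """
    loc_ret, sc_ret = preset.mfi_retained
    loc_rel, sc_rel = preset.mfi_released
    n = released.size
    out = np.empty(n)
    out[~released] = rng.normal(loc_ret, sc_ret, size=int((~released).sum()))
    out[released] = rng.normal(loc_rel, sc_rel, size=int(released.sum()))
    return np.clip(out, 0.0, None)


def simulate_tube(
    preset: GeneratorPreset,
    condition: Tuple[str, float],
    n_events: int,
    seed,
    control_role: str = "none",
) -> EventTable:
    """Simulate one tube and return its event table with truth labels.

    Parameters
    ----------
    preset
        Generator truth object.
    condition
        ``(reagent, concentration_uM)``; for pure control tubes the reagent
        is conventionally the control name itself.
    n_events
        Requested number of *target* cells; the generator oversamples raw
        events by the expected target fraction so that roughly this many
        target cells survive gating, mirroring a fixed-target acquisition.
    seed
        Integer seed or :class:`numpy.random.SeedSequence`.
    control_role
        ``none``, ``PUMA2A``, ``alamethicin`` or ``DMSO``.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    reagent, conc = condition
    p_release = resolve_release_prob(preset, reagent, conc, control_role)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.Generator(np.random.Philox(ss))

    fracs = preset.subpop_fracs
    n_raw = int(math.ceil(n_events / fracs["target"]))
    pops = rng.choice(POPULATIONS, size=n_raw, p=[fracs[p] for p in POPULATIONS])

    values = np.zeros((n_raw, len(DEFAULT_CHANNELS)), dtype=np.float64)
    col = {c: i for i, c in enumerate(DEFAULT_CHANNELS)}
    released = np.zeros(n_raw, dtype=bool)

    for pop in POPULATIONS:
        idx = np.flatnonzero(pops == pop)
        if idx.size == 0:
            continue
        n = idx.size
        sc = preset.scatter_params[pop]
        mk = preset.marker_params[pop]
        if pop == "doublet":
            # sum of two singlet scatter draws; pulse height ~ max of the two
            a1 = _lognormal(rng, sc["FSC-A"][0], sc["FSC-A"][1], n)
            a2 = _lognormal(rng, sc["FSC-A"][0], sc["FSC-A"][1], n)
            h1 = a1 * _lognormal(rng, 0.97, 0.03, n)
            h2 = a2 * _lognormal(rng, 0.97, 0.03, n)
            fsc_a = a1 + a2
            fsc_h = np.maximum(h1, h2)
            ssc_a = (_lognormal(rng, sc["SSC-A"][0], sc["SSC-A"][1], n)
                     + _lognormal(rng, sc["SSC-A"][0], sc["SSC-A"][1], n))
        else:
            fsc_a = _lognormal(rng, sc["FSC-A"][0], sc["FSC-A"][1], n)
            fsc_h = fsc_a * _lognormal(rng, 0.97, 0.03, n)
            ssc_a = _lognormal(rng, sc["SSC-A"][0], sc["SSC-A"][1], n)
        values[idx, col["FSC-A"]] = fsc_a
        values[idx, col["FSC-H"]] = fsc_h
        values[idx, col["SSC-A"]] = ssc_a
        for channel in ("Zombie", "CD5", "CD19"):
            values[idx, col[channel]] = _lognormal(rng, mk[channel][0], mk[channel][1], n)

        # release status: controls bind live cells exactly; dead cells leak
        if pop == "dead":
            if control_role == "alamethicin":
                rel = np.ones(n, dtype=bool)
            else:
                rel = rng.random(n) < max(preset.dead_release_prob, p_release)
        elif pop in ("target", "non_target", "doublet"):
            if p_release <= 0.0:
                rel = np.zeros(n, dtype=bool)
            elif p_release >= 1.0:
                rel = np.ones(n, dtype=bool)
            else:
                rel = rng.random(n) < p_release
        else:  # debris carries no mitochondria worth speaking of
            rel = np.ones(n, dtype=bool)
        released[idx] = rel

    values[:, col["CytC"]] = _cytc_draw(rng, preset, released)

    truth = pd.DataFrame({"population": pops, "released": released})
    return EventTable(DEFAULT_CHANNELS, values, truth)


def _condition_tuple(entry) -> Tuple[str, float, str]:
    """Normalize a panel entry to (reagent, concentration_uM, control_role)."""
    if isinstance(entry, str):
        if entry in ("PUMA2A", "alamethicin"):
            return (entry, 25.0 if entry == "alamethicin" else 10.0, entry)
        raise ValidationError(
            f"string panel entry {entry!r} must be a control name"
        )
    if len(entry) == 2:
        reagent, conc = entry
        role = reagent if reagent in ("PUMA2A", "alamethicin", "DMSO") else "none"
        return (str(reagent), float(conc), role)
    reagent, conc, role = entry
    return (str(reagent), float(conc), str(role))


def simulate_cohort(
    presets: Sequence[Tuple[GeneratorPreset, int]],
    panel: Sequence,
    n_events: int,
    seed: int,
    out_dir,
    n_replicates: int = 2,
    file_format: str = "fcs",
    write_csv_mirror: bool = False,
) -> Manifest:
    """Simulate a cohort of samples, write one file per tube, return the manifest.

    Parameters
    ----------
    presets
        Sequence of ``(preset, n_samples)``; each sample gets its own
        deterministic substream.
    panel
        Conditions per sample; entries are control names (``"PUMA2A"``,
        ``"alamethicin"``) or ``(reagent, concentration_uM)`` tuples.  The
        panel must include both controls.
    n_events
        Target-cell count per tube (acquisition-scale contract).
    seed
        Master integer seed.
    out_dir
        Output directory; created if missing.
    n_replicates
        Tubes per condition (assay runs duplicates by default).
    file_format
        ``"fcs"`` (FCS 3.1, float list mode) or ``"csv"``.
    write_csv_mirror
        Also write a CSV mirror (with truth columns) next to each FCS file.
    """
    conditions = [_condition_tuple(e) for e in panel]
    roles = {c[2] for c in conditions}
    if "PUMA2A" not in roles or "alamethicin" not in roles:
        raise ValidationError("panel must include PUMA2A and alamethicin controls")
    if any(n < 1 for _, n in presets):
        raise ValidationError("n_samples must be >= 1 for every preset")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: List[TubeRecord] = []
    sample_idx = 0
    for preset, n_samples in presets:
        for _ in range(n_samples):
            sample_id = f"{preset.name}_{sample_idx:02d}"
            tube_idx = 0
            for reagent, conc, role in conditions:
                for rep in range(1, n_replicates + 1):
                    ss = np.random.SeedSequence([int(seed), sample_idx, tube_idx])
                    table = simulate_tube(preset, (reagent, conc), n_events,
                                          ss, control_role=role)
                    stem = f"{sample_id}_{reagent.replace(' ', '')}_{conc:g}uM_r{rep}"
                    if file_format == "csv":
                        path = out_dir / f"{stem}.csv"
                        write_events_csv(table, path)
                    else:
                        path = out_dir / f"{stem}.fcs"
                        write_fcs(table, path)
                        if write_csv_mirror:
                            write_events_csv(table, out_dir / f"{stem}.csv")
                    records.append(TubeRecord(
                        path=str(path), sample_id=sample_id, reagent=reagent,
                        concentration_uM=conc, replicate=rep, control_role=role,
                    ))
                    tube_idx += 1
            sample_idx += 1

    manifest = Manifest(records)
    manifest.write_tsv(out_dir / "manifest.tsv")
    return manifest
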