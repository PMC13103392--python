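"""Mortality index (MI) computation for paired-sham and pooled-sham designs.

MI is the study phenotype: 100 x (proportion dead in the trauma-treated vial
minus the sham baseline proportion).  In paired designs every experimental
unit (a dam's offspring, an inbred family, ...) has its own sham vial; in
pooled designs (e.g. flies collected in mass across rearing vials) the
baseline is the average mortality across all sham vials of the group.
Negative MI is retained and MI is never clipped or variance-stabilized:
downstream t-tests operate on raw MI.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from .core_data_io import MIRecord, VialCount


class UndefinedProportionError(ValueError):
    """A vial with zero flies has no death proportion."""


class PairingError(ValueError):
    """Hit and sham vials cannot be matched as required by the design."""


def _proportion(vial: VialCount) -> float:
    if vial.n_flies == 0:
        raise UndefinedProportionError(
            f"vial {vial.unit_id!r} ({vial.treatment}) has n_flies=0")
    return vial.n_dead / vial.n_flies


def compute_mi_paired(hit: VialCount, sham: VialCount) -> MIRecord:
    """MI for one unit from its matched hit and sham vials.

    mi = 100 * (hit.n_dead/hit.n_flies - sham.n_dead/sham.n_flies)
    """
    if hit.treatment != "hit" or sham.treatment != "sham":
        raise PairingError(
            f"expected a (hit, sham) pair, got ({hit.treatment}, {sham.treatment})")
    if (hit.group_id, hit.unit_id) != (sham.group_id, sham.unit_id):
        raise PairingError(
            f"unit keys differ: ({hit.group_id}, {hit.unit_id}) vs "
            f"({sham.group_id}, {sham.unit_id})")
    mi = 100.0 * (_proportion(hit) - _proportion(sham))
    return MIRecord(group_id=hit.group_id, unit_id=hit.unit_id, mi=mi,
                    n_hit=hit.n_flies, n_sham=sham.n_flies,
                    baseline_mode="paired", block=hit.block)


def compute_mi_pooled(hit_vials: Sequence[VialCount],
                      sham_vials: Sequence[VialCount],
                      baseline: str = "vial_mean") -> list[MIRecord]:
    """MI for each hit vial against a shared sham baseline for the group.

    ``baseline="vial_mean"`` (default) averages the sham vials' death
    proportions, each vial weighted equally; ``baseline="pooled_counts"``
    divides total sham deaths by total sham flies (sensitivity alternative).
    """
    if not sham_vials:
        raise PairingError("pooled baseline requires at least one sham vial")
    groups = {v.group_id for v in list(hit_vials) + list(sham_vials)}
    if len(groups) != 1:
        raise PairingError(f"all vials must share one group_id, got {sorted(groups)}")
    for v in hit_vials:
        if v.treatment != "hit":
            raise PairingError(f"vial {v.unit_id!r} in hit set has treatment {v.treatment!r}")
    for v in sham_vials:
        if v.treatment != "sham":
            raise PairingError(f"vial {v.unit_id!r} in sham set has treatment {v.treatment!r}")
    if baseline == "vial_mean":
        props = [_proportion(v) for v in sham_vials]
        base = sum(props) / len(props)
    elif baseline == "pooled_counts":
        total = sum(v.n_flies for v in sham_vials)
        if total == 0:
            raise UndefinedProportionError("sham vials contain no flies")
        base = sum(v.n_dead for v in sham_vials) / total
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return [MIRecord(group_id=v.group_id, unit_id=v.unit_id,
                     mi=100.0 * (_proportion(v) - base),
                     n_hit=v.n_flies, n_sham=0, baseline_mode="pooled",
                     block=v.block)
            for v in hit_vials]


def family_mi(vials: Sequence[VialCount]) -> MIRecord:
    """MI for one unit (dam/family) from exactly one hit and one sham vial."""
    hits = [v for v in vials if v.treatment == "hit"]
    shams = [v for v in vials if v.treatment == "sham"]
    if len(hits) != 1 or len(shams) != 1:
        unit = vials[0].unit_id if vials else "?"
        raise PairingError(
            f"unit {unit!r}: expected exactly one hit and one sham vial, "
            f"got {len(hits)} hit / {len(shams)} sham")
    return compute_mi_paired(hits[0], shams[0])


def paired_mi_records(vials: Iterable[VialCount],
                      strict: bool = False) -> tuple[list[MIRecord], list[str]]:
    """Per-unit paired MI for a whole study, grouping vials by (group, unit).

    Units lacking a usable hit/sham pair (unpaired arms or empty vials) are
    excluded with a warning message, mirroring the exclusion of dams without
    offspring in the breeding design; ``strict=True`` raises instead.
    Returns ``(records, warnings)``.
    """
    by_unit: dict[tuple[str, str], list[VialCount]] = defaultdict(list)
    for v in vials:
        by_unit[(v.group_id, v.unit_id)].append(v)
    records: list[MIRecord] = []
    warnings: list[str] = []
    for key in by_unit:
        try:
            records.append(family_mi(by_unit[key]))
        except (PairingError, UndefinedProportionError) as err:
            if strict:
                raise
            warnings.append(f"excluded unit {key}: {err}")
    return records, warnings
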