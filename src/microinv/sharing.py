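"""MIR sharing across groups and human-primate shared inverted alleles.

* :func:`venn_sharing` partitions MIRs into the 2^k - 1 non-empty membership
  regions over k groups (a MIR belongs to a group iff at least one member
  allele comes from that group).
* :func:`classify_hits` separates singleton MIRs (exactly one MI allele)
  from non-singletons and reports per-group hit counts.
* :func:`cross_species_share` counts inverted alleles shared between human
  super-populations and other species' call sets on the same reference
  coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .detect import MICall
from .regions import MIR, AnnotationIndex, classify_mir, merge_mis_to_mirs
from .structure import GENIC_CLASSES


@dataclass
class SharingReport:
    """Membership-region counts over groups, singleton MIRs, per-group hits.

    ``region_counts`` maps a frozenset of group names (a non-empty Venn
    region) to the number of MIRs whose member alleles come from exactly
    those groups; regions are disjoint by construction and sum to the number
    of MIRs with at least one member.
    """

    region_counts: dict[frozenset, int]
    singleton_mirs: list[MIR]
    hits_by_group: dict[str, dict[str, int]]  # mir_id -> group -> allele count

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())


def _mir_group_hits(mir: MIR, group_of_individual: Mapping[str, str]) -> dict[str, int]:
    hits: dict[str, int] = {}
    for c in mir.members:
        if c.individual not in group_of_individual:
            raise ValueError(f"individual {c.individual} has no group assignment")
        g = group_of_individual[c.individual]
        hits[g] = hits.get(g, 0) + 1
    return hits


def venn_sharing(
    mirs: Sequence[MIR],
    group_of_individual: Mapping[str, str],
    gene_region_only: bool = False,
    ann: AnnotationIndex | None = None,
) -> SharingReport:
    """Count MIRs in every non-empty group-membership region."""
    if gene_region_only and ann is None:
        raise ValueError("gene_region_only requires an annotation")
    region_counts: dict[frozenset, int] = {}
    singletons: list[MIR] = []
    hits_by_group: dict[str, dict[str, int]] = {}
    for m in mirs:
        if gene_region_only and classify_mir(m, ann) not in GENIC_CLASSES:
            continue
        hits = _mir_group_hits(m, group_of_individual)
        hits_by_group[m.mir_id] = hits
        region = frozenset(hits)
        region_counts[region] = region_counts.get(region, 0) + 1
        if m.hits == 1:
            singletons.append(m)
    return SharingReport(
        region_counts=region_counts,
        singleton_mirs=singletons,
        hits_by_group=hits_by_group,
    )


def classify_hits(
    mirs: Sequence[MIR], group_of_individual: Mapping[str, str]
) -> tuple[list[MIR], list[tuple[MIR, dict[str, int]]]]:
    """Split MIRs into singletons (hits == 1) and non-singletons.

    Non-singletons are returned with their per-group hit counts, sorted by
    total hits descending (the most recurrent MIR first).
    """
    singletons = [m for m in mirs if m.hits == 1]
    non = [
        (m, _mir_group_hits(m, group_of_individual)) for m in mirs if m.hits >= 2
    ]
    non.sort(key=lambda t: (-t[0].hits, t[0].mir_id))
    return singletons, non


def _boundary_match(a, b, tolerance: int, exact: bool) -> bool:
    if a.chromosome != b.chromosome:
        return False
    if exact:
        return a.start == b.start and a.end == b.end
    return (
        a.overlaps(b)
        and abs(a.start - b.start) <= tolerance
        and abs(a.end - b.end) <= tolerance
    )


def cross_species_share(
    human_calls: Sequence[MICall],
    species_calls: Mapping[str, Sequence[MICall]],
    superpop_of_individual: Mapping[str, str],
    boundary_tolerance: int = 4,
    exact: bool = False,
) -> pd.DataFrame:
    """Counts of inverted alleles shared between species and super-populations.

    A human inverted allele is shared with a species iff some species call
    overlaps it with both boundary differences within ``boundary_tolerance``
    (or coordinates equal, with ``exact``).  Shared counts are at the level
    of distinct loci: the human calls of each super-population (and pooled)
    are merged into MIRs first and a locus counts once however many
    individuals carry it.  Rows: species (plus a Total row of species call
    counts); columns: species total, each super-population, pooled humans.

    All call sets must be on the same reference coordinate system; disjoint
    chromosome name sets are rejected.
    """
    human_chroms = {c.interval.chromosome for c in human_calls}
    superpops = sorted(set(superpop_of_individual.values()))
    groups: dict[str, list[MICall]] = {s: [] for s in superpops}
    for c in human_calls:
        if c.individual not in superpop_of_individual:
            raise ValueError(f"individual {c.individual} has no super-population assignment")
        groups[superpop_of_individual[c.individual]].append(c)

    group_mirs = {s: merge_mis_to_mirs(groups[s]) for s in superpops}
    pooled_mirs = merge_mis_to_mirs(human_calls)

    rows = []
    for species in sorted(species_calls):
        sp_calls = list(species_calls[species])
        sp_chroms = {c.interval.chromosome for c in sp_calls}
        if human_chroms and sp_chroms and not (human_chroms & sp_chroms):
            raise ValueError(
                f"species {species}: chromosome names share nothing with the human calls; "
                "mixed coordinate systems?"
            )

        def shared_loci(mirs) -> int:
            n = 0
            for m in mirs:
                if any(
                    _boundary_match(c.interval, s.interval, boundary_tolerance, exact)
                    for c in m.members
                    for s in sp_calls
                ):
                    n += 1
            return n

        row = {"species": species, "total": len(sp_calls)}
        for s in superpops:
            row[s] = shared_loci(group_mirs[s])
        row["pooled_human"] = shared_loci(pooled_mirs)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("species")
    return df
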