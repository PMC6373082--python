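"""Set operations over genotype call sets.

These operations mirror the standard congenic-line workflow: intersect
replicate samples of one genotype into a consensus, subtract or annotate
against strain reference call sets (e.g. recipient C57BL/6J or the donor
ES-cell strain), and dissect the variants linked to the knockout genotype —
the operational congenic-footprint signal — by comparing the KO consensus
against wild-type littermate calls.

All operations are key-based on :class:`~congenicscan.variants.SiteKey` and
never invent keys: every output is a subset of its primary input.  Missing
and hom_ref genotypes never count as variant evidence.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence, Union

from .variants import Genotype, GenotypeCallSet, SiteKey, VariantCall

__all__ = [
    "Concordance",
    "Origin",
    "KoLinkedReason",
    "ConsensusCallSet",
    "OriginAnnotatedSet",
    "KoLinkedSet",
    "intersect_replicates",
    "subtract_reference",
    "annotate_strain_origin",
    "dissect_ko_linked",
]


class Concordance(enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT_GENOTYPE = "discordant_genotype"


class Origin(enum.Enum):
    DONOR_DERIVED = "donor_derived"
    NOVEL = "novel"


class KoLinkedReason(enum.Enum):
    ABSENT_IN_WT = "absent_in_wt"
    GENOTYPE_MISMATCH = "genotype_mismatch"


@dataclass
class ConsensusCallSet(GenotypeCallSet):
    """Replicate consensus: calls at keys shared by every replicate, with a
    per-key concordance flag recording replicate genotype agreement."""

    concordance: dict[SiteKey, Concordance] = field(default_factory=dict)


@dataclass
class OriginAnnotatedSet(GenotypeCallSet):
    """Call set with a per-key strain-origin flag (donor_derived vs novel)."""

    origin: dict[SiteKey, Origin] = field(default_factory=dict)


@dataclass
class KoLinkedSet(GenotypeCallSet):
    """KO-linked variants: the KO-consensus calls absent from WT or present
    in WT with a different genotype state, with the retention reason."""

    reason: dict[SiteKey, KoLinkedReason] = field(default_factory=dict)


AnyCallSet = Union[GenotypeCallSet, ConsensusCallSet]

_VARIANT_STATES = {Genotype.HET, Genotype.HOM_ALT}


def intersect_replicates(
    sets: Sequence[GenotypeCallSet],
    genotype_policy: str = "strict",
) -> ConsensusCallSet:
    """Intersect replicate call sets of one genotype into a consensus.

    A key is retained iff it carries a variant genotype (het or hom_alt) in
    every replicate.  The consensus genotype follows ``genotype_policy``:

    ``strict``
        all replicate genotypes equal, otherwise the key is flagged
        ``discordant_genotype`` with consensus genotype ``missing``;
    ``majority``
        the modal genotype; ties are flagged discordant.

    QUAL and DP of the consensus call are the minima over replicates (the
    weakest supporting evidence).
    """
    if not sets:
        raise ValueError("intersect_replicates requires at least one call set")
    if genotype_policy not in ("strict", "majority"):
        raise ValueError(f"unknown genotype_policy {genotype_policy!r}")

    shared: set[SiteKey] | None = None
    for s in sets:
        keys = {c.key for c in s.variant_calls()}
        shared = keys if shared is None else shared & keys
    assert shared is not None

    label = sets[0].label
    out = ConsensusCallSet(label)
    for key in shared:
        reps = [s.calls[key] for s in sets]
        genos = [c.genotype for c in reps]
        counts = Counter(genos)
        modal, modal_n = counts.most_common(1)[0]
        unanimous = len(counts) == 1
        tied = sum(1 for n in counts.values() if n == modal_n) > 1
        if unanimous:
            genotype, flag = modal, Concordance.CONCORDANT
        elif genotype_policy == "strict":
            genotype, flag = Genotype.MISSING, Concordance.DISCORDANT_GENOTYPE
        else:  # majority
            genotype = Genotype.MISSING if tied else modal
            flag = Concordance.DISCORDANT_GENOTYPE
        quals = [c.qual for c in reps]
        depths = [c.depth for c in reps]
        out.calls[key] = VariantCall(
            key=key,
            genotype=genotype,
            qual=None if any(q is None for q in quals) else min(quals),
            depth=None if any(d is None for d in depths) else min(depths),
            sample_id=label,
        )
        out.concordance[key] = flag
    return out


def subtract_reference(callset: AnyCallSet, reference: GenotypeCallSet) -> AnyCallSet:
    """Remove every call whose SiteKey appears in ``reference``.

    Removal is site-level: the reference genotype is ignored, matching
    strain-level subtraction of e.g. recipient-strain (C57BL/6J) variants.
    """
    ref_keys = reference.keys()
    kept = {k: c for k, c in callset.calls.items() if k not in ref_keys}
    if isinstance(callset, ConsensusCallSet):
        return ConsensusCallSet(
            callset.label, kept, {k: v for k, v in callset.concordance.items() if k in kept}
        )
    return GenotypeCallSet(callset.label, kept)


def annotate_strain_origin(
    callset: AnyCallSet, donor_reference: GenotypeCallSet
) -> OriginAnnotatedSet:
    """Flag each call donor_derived (SiteKey present in the donor-strain
    reference, e.g. a Mouse Genomes Project strain VCF) or novel.

    No call is removed; with an empty donor reference everything is novel.
    """
    donor_keys = donor_reference.keys()
    out = OriginAnnotatedSet(callset.label, dict(callset.calls))
    for key in callset.calls:
        out.origin[key] = (
            Origin.DONOR_DERIVED if key in donor_keys else Origin.NOVEL
        )
    return out


def dissect_ko_linked(ko: AnyCallSet, wt: AnyCallSet) -> KoLinkedSet:
    """Extract KO-linked variants: the congenic-footprint signal.

    A KO call is retained iff its key is absent from the WT set (hom_ref or
    missing WT genotypes count as absent) or present with a different
    genotype state.  Genotype comparison is by unphased state: ``1|1``
    equals ``1/1``.  KO calls whose genotype matches WT are background shared
    by the littermates and are excluded.  The WT side may be one sample or a
    WT consensus.
    """
    out = KoLinkedSet(ko.label)
    for key, call in ko.calls.items():
        if call.genotype not in _VARIANT_STATES:
            continue
        wt_call = wt.calls.get(key)
        if wt_call is None or wt_call.genotype in (Genotype.HOM_REF, Genotype.MISSING):
            out.calls[key] = call
            out.reason[key] = KoLinkedReason.ABSENT_IN_WT
        elif wt_call.genotype is not call.genotype:
            out.calls[key] = call
            out.reason[key] = KoLinkedReason.GENOTYPE_MISMATCH
    return out
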