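"""Candidate-site extraction, labeling, class balancing and dataset splits.

Candidate residues are Asn (N-linked) or Ser/Thr (O-linked). Experimental
annotations mark positives; the remaining candidates of proteins that
contain at least one positive become negatives (candidates in proteins with
no annotated site stay unknown and are excluded from training). Negatives
are under-sampled to a 1:1 ratio against positives, and the data is split
into benchmark and independent partitions at the structure level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import SiteRecord, StructureModel

log = logging.getLogger(__name__)


def check_sequon(sequence: str, i: int) -> bool:
    """True iff the Asn at ``i`` sits in an Asn-X-Ser/Thr motif with X != Pro."""
    if sequence[i] != "N":
        raise ValueError(f"position {i} is {sequence[i]!r}, not Asn")
    return (
        i + 2 < len(sequence)
        and sequence[i + 1] != "P"
        and sequence[i + 2] in ("S", "T")
    )


def extract_candidate_sites(model: StructureModel, glyco_type: str) -> list[SiteRecord]:
    """All candidate residues of a chain as unlabeled records (Asn for
    N-linked, with sequon flag; Ser/Thr for O-linked)."""
    if glyco_type not in ("N", "O"):
        raise ValueError(f"glyco_type must be 'N' or 'O', got {glyco_type!r}")
    seq = model.sequence
    targets = ("N",) if glyco_type == "N" else ("S", "T")
    records = []
    for i, aa in enumerate(seq):
        if aa in targets:
            records.append(SiteRecord(
                structure_id=model.structure_id,
                chain=model.chain_id,
                seq_index=i,
                aa=aa,
                glyco_type=glyco_type,
                label=None,
                sequon=check_sequon(seq, i) if glyco_type == "N" else False,
            ))
    return records


def apply_labels(records: list[SiteRecord],
                 annotations: pd.DataFrame) -> list[SiteRecord]:
    """Attach experimental labels to candidate records.

    ``annotations`` has columns (structure_id, chain, seq_index, glyco_type).
    Annotated candidates become positive; other candidates in structures
    with at least one positive become negative; candidates in structures
    without any positive stay unknown. An annotation that does not resolve
    to a candidate N/S/T residue is an error.
    """
    by_key = {(r.structure_id, r.chain, r.seq_index, r.glyco_type): r for r in records}
    positives = set()
    bad = []
    for row in annotations.itertuples(index=False):
        key = (row.structure_id, row.chain, int(row.seq_index), row.glyco_type)
        if key not in by_key:
            bad.append(key)
        else:
            positives.add(key)
    if bad:
        raise ValueError(f"annotations do not match candidate residues: {bad}")
    pos_structs = {(k[0], k[1]) for k in positives}
    out = []
    for r in records:
        key = (r.structure_id, r.chain, r.seq_index, r.glyco_type)
        if key in positives:
            label = 1
            if r.glyco_type == "N" and not r.sequon:
                log.warning("positive N-site %s lacks the sequon motif", key)
        elif (r.structure_id, r.chain) in pos_structs:
            label = 0
        else:
            label = None
        out.append(SiteRecord(r.structure_id, r.chain, r.seq_index, r.aa,
                              r.glyco_type, label, r.sequon))
    return out


def undersample_negatives(records: list[SiteRecord], ratio: float = 1.0,
                          seed: int | None = None) -> list[SiteRecord]:
    """Keep all positives and a uniform random sample of
    floor(ratio * n_positives) negatives (all of them, with a warning, if
    fewer exist). Unknown-label records are dropped."""
    positives = [r for r in records if r.label == 1]
    negatives = [r for r in records if r.label == 0]
    if not positives:
        raise ValueError("no positive records to balance against")
    n_keep = int(np.floor(ratio * len(positives)))
    rng = np.random.default_rng(seed)
    if len(negatives) <= n_keep:
        if len(negatives) < n_keep:
            log.warning("only %d negatives available, wanted %d", len(negatives), n_keep)
        kept = negatives
    else:
        idx = rng.choice(len(negatives), size=n_keep, replace=False)
        kept = [negatives[i] for i in sorted(idx)]
    return positives + kept


@dataclass
class DatasetSplit:
    """Benchmark / independent partition of site records, disjoint by
    structure so no chain leaks across the boundary."""

    benchmark: list[SiteRecord]
    independent: list[SiteRecord]
    seed: int | None
    independent_fraction: float = 0.2


def split_dataset(records: list[SiteRecord], fraction: float = 0.2,
                  seed: int | None = None) -> DatasetSplit:
    """Random structure-level split: whole chains are assigned to the
    independent partition until it holds about ``fraction`` of the sites."""
    structs = sorted({r.structure_id for r in records})
    if len(structs) < 2:
        raise ValueError("need at least two distinct structures to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(structs))
    target = fraction * len(records)
    counts = {s: sum(r.structure_id == s for r in records) for s in structs}
    independent_ids: set[str] = set()
    acc = 0
    for s in order:
        if acc >= target:
            break
        independent_ids.add(s)
        acc += counts[s]
    benchmark = [r for r in records if r.structure_id not in independent_ids]
    independent = [r for r in records if r.structure_id in independent_ids]
    return DatasetSplit(benchmark=benchmark, independent=independent,
                        seed=seed, independent_fraction=fraction)


def filter_redundancy(records: list[SiteRecord],
                      clusters: dict[str, str] | None = None) -> list[SiteRecord]:
    """Optional redundancy pre-filter hook.

    ``clusters`` maps structure_id -> cluster representative id (e.g. from
    an external sequence-clustering run); only records of representative
    structures are kept. With no cluster table this is a no-op.
    """
    if clusters is None:
        return list(records)
    return [r for r in records if clusters.get(r.structure_id, r.structure_id) == r.structure_id]
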