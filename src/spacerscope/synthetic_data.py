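"""Fully labeled synthetic universes for end-to-end pipeline testing.

The generator emulates the statistical structure the pipeline assumes:
repeat clusters with planted PAM motifs at a stated adherence, planted
array orientations (a cluster may be stored reverse-complemented),
protospacers embedded inside ORF-bearing target contigs with a
configurable coding-strand bias, genus structure for the second filter
step, decoy spacers with matched fractions around the 80-90% boundary,
and array-embedded self-hits that must be caught by the array filter.
Every generated record is mirrored in a machine-readable truth bundle.

Flank background is i.i.d. at the target GC content (no dinucleotide
structure); ORF interiors are stop-free codons sampled at the same GC.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seq import BASES, gc_fraction, revcomp
from .config_io import (
    OrfAnnotation,
    SpacerRecord,
    SubjectSequence,
    write_fasta,
    write_gff,
    write_spacer_table,
)
from .cooccurrence import ArrayInfo, CasCluster, CasContext

#: default planted PAM per subtype (motif, side); None = no PAM (RNA systems)
DEFAULT_PAMS: dict[str, tuple[str, str] | None] = {
    "I-E": ("AAG", "upstream"),
    "I-B": ("TTA", "upstream"),
    "I-C": ("TTC", "upstream"),
    "I-F": ("ACC", "upstream"),
    "II-A": ("TGG", "downstream"),
    "II-C": ("AGG", "downstream"),
    "III-A": None,
    "III-B": None,
}

#: PAM a type III cluster inherits from a co-resident type I acquisition module
TRANS_ACQUIRED_PAM = ("TTC", "upstream")

_DEFAULT_SUBTYPES = ["I-E", "I-B", "II-A", "I-C", "III-B", "I-F"]

CRRNA_HANDLE = "ATTGAAAC"


@dataclass
class GeneratorParams:
    """Knobs of the synthetic universe; defaults are the study conditions."""

    n_clusters: int = 20
    spacers_per_cluster: int = 30
    repeat_len: int = 29
    spacer_len: int = 32
    subtypes: Sequence[str] | None = None          # cycled over clusters
    pam_motifs: Mapping[str, tuple[str, str] | None] | None = None
    pam_adherence: float = 0.9
    planted_orientation: Sequence[str] | None = None  # per cluster
    target_gc: float = 0.5
    substitution_rate: float = 0.02                # per base per protospacer copy
    hits_per_spacer: tuple[int, int] = (1, 3)
    hit_probability: float = 1.0                   # P(a spacer has any target)
    coding_fraction: Mapping[str, float] | None = None
    coding_fraction_default: float = 0.5
    orf_density: float = 0.3                       # P(extra decoy ORF per contig)
    n_decoy_spacers: int = 18
    n_array_embedded_hits: int = 12
    genus_labels: Sequence[str] | None = None
    iii_pam_without_cas12: bool = True             # trans-acquired PAM in cas1-2-less III
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pam_adherence", "target_gc", "substitution_rate", "hit_probability",
                     "orf_density", "coding_fraction_default"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.spacer_len < 27:
            raise ValueError("spacer_len must be >= 27 for non-decoy spacers")
        if self.hits_per_spacer[0] < 1 or self.hits_per_spacer[0] > self.hits_per_spacer[1]:
            raise ValueError("hits_per_spacer must be a (lo, hi) range with lo >= 1")

    def subtype_of(self, cluster_index: int) -> str:
        subtypes = list(self.subtypes) if self.subtypes else _DEFAULT_SUBTYPES
        return subtypes[cluster_index % len(subtypes)]

    def pam_of(self, subtype: str, has_cas12: bool) -> tuple[str, str] | None:
        table = dict(DEFAULT_PAMS)
        if self.pam_motifs:
            table.update(self.pam_motifs)
        pam = table.get(subtype)
        if pam is None and subtype.startswith("III") and self.iii_pam_without_cas12 and not has_cas12:
            return TRANS_ACQUIRED_PAM
        return pam

    def orientation_of(self, cluster_index: int) -> str:
        if self.planted_orientation:
            return self.planted_orientation[cluster_index % len(self.planted_orientation)]
        return "forward" if cluster_index % 2 == 0 else "reverse"

    def genus_of(self, cluster_index: int) -> str:
        if self.genus_labels:
            return self.genus_labels[cluster_index % len(self.genus_labels)]
        return f"Genus{cluster_index:02d}"

    def coding_fraction_of(self, subtype: str) -> float:
        if self.coding_fraction and subtype in self.coding_fraction:
            return self.coding_fraction[subtype]
        return self.coding_fraction_default


@dataclass
class UniverseTruth:
    """Ground truth for every generated record."""

    params: dict = field(default_factory=dict)
    clusters: dict[str, dict] = field(default_factory=dict)
    spacers: dict[str, dict] = field(default_factory=dict)
    hits: list[dict] = field(default_factory=list)
    orfs: dict[str, list] = field(default_factory=dict)


@dataclass
class Universe:
    records: list[SpacerRecord]
    subjects: list[SubjectSequence]
    orfs: list[OrfAnnotation]
    contexts: list[CasContext]
    truth: UniverseTruth


# ---------------------------------------------------------------------------
# sequence sampling
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=n, p=probs))


_STOPS = {"TAA", "TAG", "TGA"}


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Stop-free codons sampled base-wise at the target GC."""
    out = []
    while len(out) < n_codons:
        codon = _random_seq(rng, 3, gc)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    out, n_sub = [], 0
    for base in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != base]))
            n_sub += 1
        else:
            out.append(base)
    return "".join(out), n_sub


def _mutate_exactly(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def _realized_identities(query: str, subject: str) -> int:
    """Identities of the best infix alignment, as the matcher counts them."""
    import edlib

    result = edlib.align(query, subject, mode="HW", task="path")
    if result["editDistance"] < 0:
        return 0
    return edlib.getNiceAlignment(result, query, subject)["matched_aligned"].count("|")


def _flanks_clear_of_repeats(
    seq: str, start: int, end: int, repeats: list[str], threshold: int = 13
) -> bool:
    from ._align import overlap_identity_score

    up, down = seq[max(0, start - 23):start], seq[end:end + 23]
    for repeat in repeats:
        for rep in (repeat, revcomp(repeat)):
            for flank in (up, down):
                if flank and overlap_identity_score(rep, flank) > threshold:
                    return False
    return True


# ---------------------------------------------------------------------------
# protospacer placement
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    subject_sequence: str
    orf: tuple[int, int, str]
    extra_orfs: list[tuple[int, int, str]]
    hit_start: int
    hit_end: int
    hit_strand: str
    pam_planted: bool


def plant_protospacers(
    rng: np.random.Generator,
    proto: str,
    pam: tuple[str, str] | None,
    strand_class: str,
    params: GeneratorParams,
    adherent: bool = True,
) -> Placement:
    """Build one target contig with the protospacer planted inside an ORF.

    The spacer-identical strand equals the ORF template strand when
    ``strand_class`` is 'coding' (so the crRNA can base-pair the mRNA) and
    the coding strand otherwise.  When ``pam`` is given and ``adherent``,
    the motif is written immediately 5' (upstream) or 3' (downstream) of
    the protospacer on the spacer-identical strand.
    """
    gc = params.target_gc
    orf_strand = "+" if rng.random() < 0.5 else "-"
    # the protospacer plus a full i.i.d. flank window on each side; the PAM
    # overwrites the proximal positions of its side when adherent
    flank = 23
    up_block = _random_seq(rng, flank, gc)
    down_block = _random_seq(rng, flank, gc)
    if pam is not None and adherent:
        motif, side = pam
        if side == "upstream":
            up_block = up_block[: flank - len(motif)] + motif
        else:
            down_block = motif + down_block[len(motif):]
    region_s = up_block + proto + down_block
    p_off = flank

    n_codons = int(rng.integers(55, 90))
    orf_seq = "ATG" + _random_codons(rng, n_codons, gc) + "TAA"
    L = len(orf_seq)
    if L - 12 - len(region_s) < 12:
        raise ValueError("ORF too short for protospacer placement")

    # spacer-identical strand: template for coding-strand targeting
    s_is_coding = strand_class == "template"
    region_cs = region_s if s_is_coding else revcomp(region_s)
    i = int(rng.integers(9, L - 9 - len(region_cs)))
    orf_seq = orf_seq[:i] + region_cs + orf_seq[i + len(region_cs):]

    if s_is_coding:
        a, b = i + p_off, i + p_off + len(proto)
    else:
        a = i + len(region_cs) - p_off - len(proto)
        b = i + len(region_cs) - p_off

    left = _random_seq(rng, int(rng.integers(40, 120)), gc)
    right = _random_seq(rng, int(rng.integers(40, 120)), gc)
    block = orf_seq if orf_strand == "+" else revcomp(orf_seq)
    if orf_strand == "+":
        start, end = len(left) + a, len(left) + b
    else:
        start, end = len(left) + L - b, len(left) + L - a
    hit_strand = orf_strand if s_is_coding else ("-" if orf_strand == "+" else "+")

    extra_orfs: list[tuple[int, int, str]] = []
    tail = ""
    if rng.random() < params.orf_density:
        gap = _random_seq(rng, int(rng.integers(20, 60)), gc)
        extra = "ATG" + _random_codons(rng, int(rng.integers(30, 50)), gc) + "TAA"
        offset = len(left) + L + len(right) + len(gap)
        extra_orfs.append((offset, offset + len(extra), "+"))
        tail = gap + extra + _random_seq(rng, 20, gc)

    subject = left + block + right + tail
    check = subject[start:end]
    if (check if hit_strand == "+" else revcomp(check)) != proto:
        raise AssertionError("protospacer placement is inconsistent")
    return Placement(
        subject_sequence=subject,
        orf=(len(left), len(left) + L, orf_strand),
        extra_orfs=extra_orfs,
        hit_start=start,
        hit_end=end,
        hit_strand=hit_strand,
        pam_planted=bool(pam) and adherent,
    )


# ---------------------------------------------------------------------------
# universe generation
# ---------------------------------------------------------------------------

def _cluster_repeat(rng: np.random.Generator, params: GeneratorParams, subtype: str,
                    existing: list[str]) -> str:
    """A fresh cluster repeat, < 80% identical to every existing one.

    Type I/III repeats end with the crRNA 5'-handle motif ATTGAAAC.
    """
    with_handle = subtype.split("-")[0] in ("I", "III")
    for _ in range(100):
        if with_handle and params.repeat_len > len(CRRNA_HANDLE) + 4:
            repeat = _random_seq(rng, params.repeat_len - len(CRRNA_HANDLE), 0.5) + CRRNA_HANDLE
        else:
            repeat = _random_seq(rng, params.repeat_len, 0.5)
        too_close = any(
            len(r) == len(repeat)
            and sum(1 for x, y in zip(r, repeat) if x == y) / len(r) >= 0.8
            for r in existing
        )
        if not too_close:
            return repeat
    raise RuntimeError("could not draw a sufficiently distinct repeat")


def generate_universe(params: GeneratorParams | None = None) -> Universe:
    """Generate a deterministic labeled universe for the given parameters."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.rng_seed)

    records: list[SpacerRecord] = []
    subjects: list[SubjectSequence] = []
    orfs: list[OrfAnnotation] = []
    contexts: list[CasContext] = []
    truth = UniverseTruth(params=dataclasses.asdict(params))

    seen_spacers: set[str] = set()
    cluster_repeats: list[str] = []
    subject_counter = 0
    anchor_pool: list[tuple[str, str, str]] = []  # (spacer_id, true_spacer, genus)

    def new_subject(seq: str, source: str = "nucleotide_db") -> str:
        nonlocal subject_counter
        sid = f"S{subject_counter:05d}"
        subject_counter += 1
        subjects.append(SubjectSequence(sid, seq, source))
        return sid

    for c in range(params.n_clusters):
        subtype = params.subtype_of(c)
        genus = params.genus_of(c)
        orientation = params.orientation_of(c)
        accession = f"G{c:03d}"
        is_iii = subtype.split("-")[0] in ("III", "VI")
        has_cas12 = (c // max(1, len(params.subtypes or _DEFAULT_SUBTYPES))) % 2 == 1 if is_iii else True
        pam = params.pam_of(subtype, has_cas12)
        repeat = _cluster_repeat(rng, params, subtype, cluster_repeats)
        cluster_repeats.append(repeat)
        coding_frac = params.coding_fraction_of(subtype)

        cas_clusters = [CasCluster(subtype, has_cas12, 14000, 20000)]
        if is_iii and not has_cas12 and params.iii_pam_without_cas12:
            # the trans-acting type I acquisition module living in the genome
            cas_clusters.append(CasCluster("I-C", True, 22000, 28000))
        contexts.append(
            CasContext(
                host_accession=accession,
                cas_clusters=cas_clusters,
                arrays=[ArrayInfo(f"arr{c:03d}", f"planted{c:03d}", 10000, 12000)],
            )
        )

        member_ids: list[str] = []
        for s in range(params.spacers_per_cluster):
            spacer_id = f"sp{c:03d}_{s:03d}"
            while True:
                true_spacer = _random_seq(rng, params.spacer_len, params.target_gc)
                if true_spacer not in seen_spacers:
                    seen_spacers.add(true_spacer)
                    break
            member_repeat = repeat if rng.random() < 0.7 else _mutate_exactly(rng, repeat, 1)
            stored_spacer = true_spacer if orientation == "forward" else revcomp(true_spacer)
            stored_repeat = member_repeat if orientation == "forward" else revcomp(member_repeat)
            cas = frozenset({subtype} | ({"I-C"} if is_iii and not has_cas12 else set()))
            records.append(
                SpacerRecord(
                    spacer_id=spacer_id,
                    sequence=stored_spacer,
                    repeat=stored_repeat,
                    host_accession=accession,
                    genus=genus,
                    taxonomy={"Genus": genus},
                    array_id=f"arr{c:03d}",
                    position_in_array=s,
                    subtype=subtype,
                    cas_genes=cas,
                )
            )
            member_ids.append(spacer_id)

            has_target = rng.random() < params.hit_probability
            strand_class = None
            if has_target:
                strand_class = "coding" if rng.random() < coding_frac else "template"
                n_hits = int(rng.integers(params.hits_per_spacer[0], params.hits_per_spacer[1] + 1))
                for _ in range(n_hits):
                    proto, n_sub = _mutate(rng, true_spacer, params.substitution_rate)
                    adherent = rng.random() < params.pam_adherence
                    placement = plant_protospacers(rng, proto, pam, strand_class, params, adherent)
                    sid = new_subject(placement.subject_sequence)
                    orf_list = [placement.orf] + placement.extra_orfs
                    orfs.extend(OrfAnnotation(sid, a, b, st) for a, b, st in orf_list)
                    truth.orfs[sid] = [list(o) for o in orf_list]
                    frac = (params.spacer_len - n_sub) / params.spacer_len
                    truth.hits.append(
                        {
                            "spacer_id": spacer_id,
                            "subject_id": sid,
                            "s_start": placement.hit_start,
                            "s_end": placement.hit_end,
                            "strand": placement.hit_strand,
                            "provenance": "genuine",
                            "n_sub": n_sub,
                            "pam_adherent": placement.pam_planted,
                            "expected_kept_step": "step1" if frac > 0.90 else "dropped",
                        }
                    )
                anchor_pool.append((spacer_id, true_spacer, genus))
            truth.spacers[spacer_id] = {
                "cluster": f"planted{c:03d}",
                "genus": genus,
                "has_target": has_target,
                "strand_class": strand_class,
                "true_spacer": true_spacer,
            }

        truth.clusters[f"planted{c:03d}"] = {
            "subtype": subtype,
            "genus": genus,
            "accession": accession,
            "repeat": repeat,
            "pam": {"motif": pam[0], "side": pam[1], "adherence": params.pam_adherence} if pam else None,
            "orientation": orientation,
            "has_cas1_cas2": has_cas12,
            "member_spacer_ids": member_ids,
        }

    # decoy spacers around the two-step filter boundary
    for d in range(params.n_decoy_spacers):
        spacer_id = f"decoy{d:03d}"
        while True:
            seq = _random_seq(rng, params.spacer_len, params.target_gc)
            if seq not in seen_spacers:
                seen_spacers.add(seq)
                break
        genus = params.genus_of(d % max(1, params.n_clusters))
        repeat = _random_seq(rng, params.repeat_len, 0.5)
        records.append(
            SpacerRecord(
                spacer_id=spacer_id,
                sequence=seq,
                repeat=repeat,
                host_accession=f"GD{d:03d}",
                genus=genus,
                taxonomy={"Genus": genus},
                array_id=f"darr{d:03d}",
            )
        )
        pattern = d % 3
        gc = params.target_gc
        # substitutions confined to the first 20 nt leave an intact 12-mer
        # for seeding; construction is re-drawn until the planted matched
        # fraction is realized exactly and no flank trips the array test,
        # so the decoy exercises the fraction filter and nothing else
        n_sub = 3 if pattern == 0 else 4  # 29/32 = 0.906 vs 28/32 = 0.875
        if pattern == 1 and anchor_pool:
            anchor_id, anchor_seq, anchor_genus = anchor_pool[d % len(anchor_pool)]
            records[-1].genus = anchor_genus  # rescue needs a same-genus anchor
            records[-1].taxonomy["Genus"] = anchor_genus
            expected = "step2"
        else:
            anchor_id = anchor_seq = None
            expected = "step1" if pattern == 0 else "dropped"
        for _ in range(100):
            positions = rng.choice(20, size=n_sub, replace=False)
            proto = list(seq)
            for p in positions:
                proto[p] = rng.choice([b for b in BASES if b != proto[p]])
            proto = "".join(proto)
            if anchor_seq is not None:
                left = _random_seq(rng, 50, gc)
                seq_full = (left + anchor_seq + _random_seq(rng, 60, gc)
                            + proto + _random_seq(rng, 50, gc))
                a0, start = len(left), len(left) + params.spacer_len + 60
            else:
                left = _random_seq(rng, 60, gc)
                seq_full = left + proto + _random_seq(rng, 60, gc)
                a0, start = None, len(left)
            end = start + params.spacer_len
            ok = (_realized_identities(seq, seq_full) == params.spacer_len - n_sub
                  and _flanks_clear_of_repeats(seq_full, start, end, [repeat]))
            if ok and anchor_seq is not None:
                anchor_repeat = next(r.repeat for r in records if r.spacer_id == anchor_id)
                ok = (_realized_identities(anchor_seq, seq_full) == params.spacer_len
                      and _flanks_clear_of_repeats(
                          seq_full, a0, a0 + params.spacer_len, [anchor_repeat]))
            if ok:
                break
        else:
            raise RuntimeError("could not construct a clean decoy placement")
        sid = new_subject(seq_full)
        if anchor_seq is not None:
            truth.hits.append(
                {
                    "spacer_id": anchor_id,
                    "subject_id": sid,
                    "s_start": a0,
                    "s_end": a0 + params.spacer_len,
                    "strand": "+",
                    "provenance": "genuine",
                    "n_sub": 0,
                    "pam_adherent": False,
                    "expected_kept_step": "step1",
                }
            )
        truth.hits.append(
            {
                "spacer_id": spacer_id,
                "subject_id": sid,
                "s_start": start,
                "s_end": start + params.spacer_len,
                "strand": "+",
                "provenance": "decoy",
                "n_sub": n_sub,
                "pam_adherent": False,
                "expected_kept_step": expected,
            }
        )
        truth.spacers[spacer_id] = {
            "cluster": "decoy",
            "genus": records[-1].genus,
            "has_target": True,
            "strand_class": None,
            "true_spacer": seq,
        }

    # array-embedded self-hits: spacer flanked by its own repeats
    members = [r for r in records if not r.spacer_id.startswith("decoy")]
    for a in range(params.n_array_embedded_hits):
        record = members[(a * 7) % len(members)]
        gc = params.target_gc
        left = _random_seq(rng, 60, gc)
        seq_full = left + record.repeat + record.sequence + record.repeat + _random_seq(rng, 60, gc)
        sid = new_subject(seq_full)
        start = len(left) + len(record.repeat)
        truth.hits.append(
            {
                "spacer_id": record.spacer_id,
                "subject_id": sid,
                "s_start": start,
                "s_end": start + len(record.sequence),
                "strand": "+",
                "provenance": "array_embedded",
                "n_sub": 0,
                "pam_adherent": False,
                "expected_kept_step": "dropped",
            }
        )

    return Universe(records, subjects, orfs, contexts, truth)


# ---------------------------------------------------------------------------
# compatibility cohort
# ---------------------------------------------------------------------------

def generate_compatibility_cohort(
    n_per_category: int = 5, n_negative: int = 5, rng_seed: int = 0
) -> tuple[list[CasContext], dict[str, tuple[str, str]], dict[str, int | str]]:
    """Genomes planting the three compatibility organizations plus negatives.

    Returns (contexts, pam_catalog mapping repeat_cluster_id ->
    (motif, subtype), truth mapping accession -> planted category).
    """
    contexts: list[CasContext] = []
    catalog: dict[str, tuple[str, str]] = {}
    labels: dict[str, int | str] = {}
    counter = 0

    def rc(motif: str, subtype: str) -> str:
        nonlocal counter
        name = f"cc_rc{counter:03d}"
        counter += 1
        catalog[name] = (motif, subtype)
        return name

    for i in range(n_per_category):
        acc = f"CAT1_{i:02d}"  # two DNA systems, own repeats, shared PAM
        rc_a, rc_b = rc("TTC", "I-A"), rc("TTC", "I-B")
        contexts.append(CasContext(acc, [
            CasCluster("I-A", True, 5000, 11000),
            CasCluster("I-B", True, 80000, 86000),
        ], [
            ArrayInfo(f"{acc}_a", rc_a, 12000, 14000),
            ArrayInfo(f"{acc}_b", rc_b, 90000, 92000),
        ]))
        labels[acc] = 1

        acc = f"CAT2_{i:02d}"  # DNA + RNA systems, distinct repeats, shared PAM
        rc_a, rc_b = rc("TTC", "I-B"), rc("TTC", "III-B")
        contexts.append(CasContext(acc, [
            CasCluster("I-B", True, 5000, 11000),
            CasCluster("III-B", False, 80000, 86000),
        ], [
            ArrayInfo(f"{acc}_a", rc_a, 12000, 14000),
            ArrayInfo(f"{acc}_b", rc_b, 90000, 92000),
        ]))
        labels[acc] = 2

        acc = f"CAT3_{i:02d}"  # one repeat cluster serving two subtypes' machinery
        rc_a = rc("TTC", "I-B")
        contexts.append(CasContext(acc, [
            CasCluster("I-B", True, 5000, 11000),
            CasCluster("III-A", False, 20000, 26000),
        ], [
            ArrayInfo(f"{acc}_a", rc_a, 13000, 15000),
        ]))
        labels[acc] = 3

    for i in range(n_negative):
        acc = f"NEG_{i:02d}"
        if i % 2 == 0:  # two DNA systems with different PAMs
            rc_a, rc_b = rc("AAG", "I-E"), rc("ACC", "I-F")
            contexts.append(CasContext(acc, [
                CasCluster("I-E", True, 5000, 11000),
                CasCluster("I-F", True, 80000, 86000),
            ], [
                ArrayInfo(f"{acc}_a", rc_a, 12000, 14000),
                ArrayInfo(f"{acc}_b", rc_b, 90000, 92000),
            ]))
        else:  # shared machinery but a second array claims the same cas clusters
            rc_a, rc_b = rc("TTC", "I-B"), rc("GGA", "I-C")
            contexts.append(CasContext(acc, [
                CasCluster("I-B", True, 5000, 11000),
                CasCluster("III-A", False, 20000, 26000),
            ], [
                ArrayInfo(f"{acc}_a", rc_a, 13000, 15000),
                ArrayInfo(f"{acc}_b", rc_b, 27000, 29000),
            ]))
        labels[acc] = "none"

    return contexts, catalog, labels


# ---------------------------------------------------------------------------
# flank-cluster generator (profile-level benchmarks)
# ---------------------------------------------------------------------------

def generate_flank_cluster(
    rng: np.random.Generator,
    n_protospacers: int = 30,
    pam: tuple[str, str] | None = ("AAG", "upstream"),
    adherence: float = 0.9,
    gc: float = 0.5,
    flank_len: int = 23,
) -> dict[str, tuple[str, str]]:
    """Consensus-flank pairs with a planted PAM, for profile benchmarks.

    Flank background is i.i.d. at ``gc``; with probability ``adherence``
    a protospacer carries the full motif at the planted side's proximal
    positions.
    """
    pairs: dict[str, tuple[str, str]] = {}
    for i in range(n_protospacers):
        up = _random_seq(rng, flank_len, gc)
        down = _random_seq(rng, flank_len, gc)
        if pam is not None and rng.random() < adherence:
            motif, side = pam
            if side == "upstream":
                up = up[: flank_len - len(motif)] + motif
            else:
                down = motif + down[len(motif):]
        pairs[f"p{i:04d}"] = (up, down)
    return pairs


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_truth_bundle(truth: UniverseTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=1, sort_keys=True))


def read_truth_bundle(path: str | Path) -> UniverseTruth:
    data = json.loads(Path(path).read_text())
    return UniverseTruth(**data)


def write_context_table(contexts: Sequence[CasContext], path: str | Path) -> None:
    """Flat CSV of arrays and cas clusters, one feature per row."""
    import pandas as pd

    rows = []
    for ctx in contexts:
        for cc in ctx.cas_clusters:
            rows.append({
                "accession": ctx.host_accession, "kind": "cas", "feature_id": "",
                "subtype": cc.subtype, "has_cas1_cas2": int(cc.has_cas1_cas2),
                "start": cc.start, "end": cc.end, "repeat_cluster": "",
            })
        for arr in ctx.arrays:
            rows.append({
                "accession": ctx.host_accession, "kind": "array", "feature_id": arr.array_id,
                "subtype": "", "has_cas1_cas2": "",
                "start": arr.start, "end": arr.end, "repeat_cluster": arr.repeat_cluster_id,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_context_table(path: str | Path) -> list[CasContext]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"accession": str, "kind": str}, keep_default_na=False)
    contexts: dict[str, CasContext] = {}
    for row in df.itertuples(index=False):
        ctx = contexts.setdefault(row.accession, CasContext(row.accession))
        if row.kind == "cas":
            ctx.cas_clusters.append(
                CasCluster(row.subtype, bool(int(row.has_cas1_cas2)), int(row.start), int(row.end))
            )
        else:
            ctx.arrays.append(
                ArrayInfo(row.feature_id, row.repeat_cluster, int(row.start), int(row.end))
            )
    return list(contexts.values())


def write_universe(universe: Universe, out_dir: str | Path) -> None:
    """Write spacers.csv, subjects.fasta, orfs.gff3, context.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spacer_table(universe.records, out / "spacers.csv")
    write_fasta(universe.subjects, out / "subjects.fasta")
    write_gff(universe.orfs, out / "orfs.gff3")
    write_context_table(universe.contexts, out / "context.csv")
    write_truth_bundle(universe.truth, out / "truth.json")
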