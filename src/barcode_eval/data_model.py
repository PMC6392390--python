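"""Domain types and IO for multi-locus barcode datasets.

A dataset couples per-locus alignments (FASTA) with a specimen metadata table
(TSV) carrying the morphological identification at species/genus/family/order
rank and, optionally, a per-locus molecular identification. All cohort-defining
operations (end trimming, locus concatenation, minimum-representative
filtering) live here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Characters accepted in aligned barcode sequences. 'N' and '?' are missing
#: data, '-' is an alignment gap; all three count as non-coverage.
IUPAC_ALPHABET = frozenset("ACGTN-?")
MISSING_CHARS = frozenset("N-?")

RANKS = ("species", "genus", "family", "order")


def _norm(label: str | None) -> str:
    return " ".join(str(label).split()) if label is not None else ""


@dataclass(frozen=True)
class TaxonLabel:
    """A taxonomic assignment at up to four nested ranks.

    Empty strings mean "not assigned at this rank". A species implies a genus
    and a genus implies a family; comparisons are case-insensitive after
    whitespace normalization.
    """

    species: str = ""
    genus: str = ""
    family: str = ""
    order: str = ""

    def __post_init__(self) -> None:
        for name in RANKS:
            object.__setattr__(self, name, _norm(getattr(self, name)))
        if self.species and not self.genus:
            raise ValueError(f"species {self.species!r} without a genus")
        if self.genus and not self.family:
            raise ValueError(f"genus {self.genus!r} without a family")

    def at_rank(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def matches_at(self, other: "TaxonLabel", rank: str) -> bool:
        """True when both labels are assigned and equal at ``rank``."""
        a, b = self.at_rank(rank), other.at_rank(rank)
        return bool(a) and bool(b) and a.casefold() == b.casefold()

    def deepest_match(self, other: "TaxonLabel") -> str | None:
        """Deepest of species/genus/family at which the labels agree."""
        for rank in ("species", "genus", "family"):
            if self.matches_at(other, rank):
                return rank
        return None

    def is_empty(self) -> bool:
        return not any(getattr(self, r) for r in RANKS)


@dataclass
class SpecimenRecord:
    """One physical specimen: morphology plus per-locus sequences/labels."""

    specimen_id: str
    morph: TaxonLabel
    molecular_by_locus: dict[str, TaxonLabel] = field(default_factory=dict)
    sequence_by_locus: dict[str, str] = field(default_factory=dict)


@dataclass
class LocusAlignment:
    """An aligned set of sequences for one locus.

    ``members`` is an ordered list of (specimen_id, gapped sequence); every
    sequence has the same length. ``locus_offsets`` records, for concatenated
    alignments, the half-open column span of each constituent locus.
    """

    locus: str
    members: list[tuple[str, str]]
    locus_offsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.members]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate specimen id {dup!r} in alignment {self.locus!r}")
        lengths = {len(s) for _, s in self.members}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged alignment {self.locus!r}: lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.members[0][1]) if self.members else 0

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.members]

    def sequence(self, specimen_id: str) -> str:
        for sid, seq in self.members:
            if sid == specimen_id:
                return seq
        raise KeyError(specimen_id)


@dataclass
class MultiLocusDataset:
    specimens: list[SpecimenRecord]
    alignments: dict[str, LocusAlignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate specimen_id {dup!r}")
        known = set(ids)
        for aln in self.alignments.values():
            for sid in aln.ids:
                if sid not in known:
                    raise ValueError(
                        f"alignment {aln.locus!r} member {sid!r} absent from specimen table"
                    )

    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen_id for s in self.specimens]

    def by_id(self, specimen_id: str) -> SpecimenRecord:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def labels(self) -> dict[str, TaxonLabel]:
        return {s.specimen_id: s.morph for s in self.specimens}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _validate_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_ALPHABET:
            # 1-based position in user-facing message
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {ch!r} at position {pos + 1}"
            )
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    return seq


def _label_from_row(row: Mapping[str, object], prefix: str = "") -> TaxonLabel:
    def get(col: str) -> str:
        v = row.get(prefix + col, "")
        return "" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v)

    return TaxonLabel(
        species=get("species"), genus=get("genus"), family=get("family"), order=get("order")
    )


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if "specimen_id" not in df.columns:
        raise ValueError("metadata table lacks a 'specimen_id' column")
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate specimen_id {dup.iloc[0]!r} in metadata")
    return df


def read_dataset(
    fasta_paths: Mapping[str, str | Path], metadata_path: str | Path
) -> MultiLocusDataset:
    """Load per-locus FASTA alignments plus the specimen metadata TSV.

    Specimens present in the metadata but absent from every FASTA are retained
    with empty sequence maps. A FASTA id missing from the metadata, a duplicate
    specimen id, or a non-IUPAC character is a hard error.
    """
    df = read_metadata(metadata_path)
    specimens: dict[str, SpecimenRecord] = {}
    for _, row in df.iterrows():
        sid = row["specimen_id"]
        morph = _label_from_row(row)
        mol: dict[str, TaxonLabel] = {}
        for col in df.columns:
            if col.startswith("molecular_") and col.endswith("_species"):
                locus = col[len("molecular_"):-len("_species")]
                lab = _label_from_row(row, prefix=f"molecular_{locus}_")
                if not lab.is_empty():
                    mol[locus] = lab
        specimens[sid] = SpecimenRecord(specimen_id=sid, morph=morph, molecular_by_locus=mol)

    alignments: dict[str, LocusAlignment] = {}
    for locus, path in fasta_paths.items():
        members: list[tuple[str, str]] = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id not in specimens:
                raise ValueError(
                    f"FASTA id {rec.id!r} in {path} is missing from the metadata table"
                )
            seq = _validate_sequence(str(rec.seq), rec.id)
            members.append((rec.id, seq))
            specimens[rec.id].sequence_by_locus[locus] = seq
        alignments[locus] = LocusAlignment(locus=locus, members=members)
    return MultiLocusDataset(specimens=list(specimens.values()), alignments=alignments)


def write_dataset(ds: MultiLocusDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one FASTA per locus plus the metadata TSV; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for locus, aln in ds.alignments.items():
        path = out / f"{locus}.fasta"
        records = [
            SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.members
        ]
        SeqIO.write(records, str(path), "fasta")
        written[f"fasta:{locus}"] = path

    loci = sorted(ds.alignments)
    rows = []
    for s in ds.specimens:
        row: dict[str, str] = {"specimen_id": s.specimen_id}
        for rank in RANKS:
            row[rank] = s.morph.at_rank(rank)
        for locus in loci:
            lab = s.molecular_by_locus.get(locus)
            for rank in ("species", "genus", "family"):
                row[f"molecular_{locus}_{rank}"] = lab.at_rank(rank) if lab else ""
        rows.append(row)
    meta_path = out / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    written["metadata"] = meta_path
    return written


# ---------------------------------------------------------------------------
# Cohort-defining operations
# ---------------------------------------------------------------------------

def trim_alignment_ends(aln: LocusAlignment, min_coverage: float = 0.5) -> LocusAlignment:
    """Strip leading/trailing columns with coverage below ``min_coverage``.

    Coverage of a column is the fraction of member sequences whose character is
    not a gap ('-') or missing ('N'/'?'). Interior low-coverage columns are
    kept; only the ragged ends are removed. Idempotent.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    if not aln.members:
        raise ValueError("empty alignment")
    n = len(aln.members)
    cov = [
        sum(1 for _, s in aln.members if s[col] not in MISSING_CHARS) / n
        for col in range(aln.length)
    ]
    start, stop = 0, aln.length
    while start < stop and cov[start] < min_coverage:
        start += 1
    while stop > start and cov[stop - 1] < min_coverage:
        stop -= 1
    if start >= stop:
        raise ValueError("empty alignment after trimming")
    offsets = {}
    if aln.locus_offsets:
        for loc, (a, b) in aln.locus_offsets.items():
            a2, b2 = max(a, start) - start, min(b, stop) - start
            if b2 > a2:
                offsets[loc] = (a2, b2)
    return LocusAlignment(
        locus=aln.locus,
        members=[(sid, s[start:stop]) for sid, s in aln.members],
        locus_offsets=offsets,
    )


def concatenate_loci(ds: MultiLocusDataset, loci: Sequence[str]) -> LocusAlignment:
    """Concatenate alignments column-wise for specimens covering every locus.

    Only specimens that have a sequence at all requested loci are included
    (the rest are dropped, mirroring a complete-case multi-locus design).
    Locus boundaries are recorded in ``locus_offsets``.
    """
    if not loci:
        raise ValueError("no loci requested")
    for locus in loci:
        if locus not in ds.alignments:
            raise ValueError(f"locus {locus!r} not present in dataset")
    shared = [
        s.specimen_id
        for s in ds.specimens
        if all(s.specimen_id in ds.alignments[loc].ids for loc in loci)
    ]
    if not shared:
        raise ValueError(f"no specimen has sequences at every locus in {list(loci)}")
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for locus in loci:
        L = ds.alignments[locus].length
        offsets[locus] = (pos, pos + L)
        pos += L
    seq_maps = {loc: dict(ds.alignments[loc].members) for loc in loci}
    members = [
        (sid, "".join(seq_maps[loc][sid] for loc in loci)) for sid in shared
    ]
    return LocusAlignment(locus="+".join(loci), members=members, locus_offsets=offsets)


def species_counts(ds: MultiLocusDataset) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in ds.specimens:
        sp = s.morph.species
        if sp:
            counts[sp] = counts.get(sp, 0) + 1
    return counts


def filter_min_representatives(
    ds: MultiLocusDataset, k: int = 2, rank: str = "species"
) -> MultiLocusDataset:
    """Retain only specimens whose morphological taxon has >= k representatives."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if k < 1:
        raise ValueError("k must be positive")
    counts: dict[str, int] = {}
    for s in ds.specimens:
        t = s.morph.at_rank(rank)
        counts[t] = counts.get(t, 0) + 1
    keep = {
        s.specimen_id
        for s in ds.specimens
        if s.morph.at_rank(rank) and counts[s.morph.at_rank(rank)] >= k
    }
    return subset_dataset(ds, keep)


def subset_dataset(ds: MultiLocusDataset, keep_ids: Iterable[str]) -> MultiLocusDataset:
    """Restrict a dataset to ``keep_ids`` (input order preserved)."""
    keep = set(keep_ids)
    specimens = [dataclasses.replace(s) for s in ds.specimens if s.specimen_id in keep]
    alignments = {
        locus: LocusAlignment(
            locus=locus,
            members=[(sid, seq) for sid, seq in aln.members if sid in keep],
            locus_offsets=dict(aln.locus_offsets),
        )
        for locus, aln in ds.alignments.items()
    }
    return MultiLocusDataset(specimens=specimens, alignments=alignments)
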