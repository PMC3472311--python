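"""Genome/annotation I/O: FASTA + GFF3 in, proteomes out.

Internal convention is 0-based half-open coordinates on the forward
strand; GFF3 (1-based inclusive) is converted at the boundary.  The
GFF3 file is authoritative for feature naming.  Translation uses the
bacterial genetic code (table 11) with ATG/GTG/TTG accepted as starts;
an internal stop codon in an annotated CDS is kept as a ``*`` marker in
the protein and the feature flagged, which downstream pseudogene
classification consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (CDS or tRNA), 0-based half-open span."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    kind: str  # "CDS" | "tRNA"
    raw_status: str = "called_full"  # "called_full" | "called_partial"
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span for {self.id}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.id}: {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Replicon:
    name: str
    length: int
    circular: bool = False
    kind: str = "chromosome"  # "chromosome" | "plasmid"


@dataclass
class StrainAnnotation:
    """One strain's replicons, gene features and proteome."""

    strain_id: str
    replicons: list[Replicon]
    features: list[GeneFeature]
    sequences: dict[str, str]
    proteome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        order = {r.name: i for i, r in enumerate(self.replicons)}
        self.features = sorted(self.features, key=lambda f: (order[f.replicon], f.start))
        for f in self.features:
            if f.end > order_len(self.replicons, f.replicon):
                raise ValueError(
                    f"{f.id}: span [{f.start}, {f.end}) exceeds replicon "
                    f"{f.replicon} length"
                )

    @property
    def cds(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]

    @property
    def trnas(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "tRNA"]

    def feature_seq(self, f: GeneFeature) -> str:
        s = self.sequences[f.replicon][f.start:f.end]
        return str(Seq(s).reverse_complement()) if f.strand == "-" else s

    def chromosome_names(self) -> set[str]:
        return {r.name for r in self.replicons if r.kind == "chromosome"}


def order_len(replicons: Iterable[Replicon], name: str) -> int:
    for r in replicons:
        if r.name == name:
            return r.length
    raise KeyError(name)


def translate_cds(nt: str, partial: bool = False) -> str:
    """Translate a coding sequence (table 11, alternative starts -> M).

    The terminal stop is stripped; internal stops stay as ``*``.
    """
    usable = len(nt) - len(nt) % 3
    aa = str(Seq(nt[:usable]).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if nt[:3] in START_CODONS and aa:
        aa = "M" + aa[1:]
    return aa


def _translate_feature(seq: str, f: GeneFeature) -> tuple[str, GeneFeature]:
    partial = f.length % 3 != 0
    cds = seq
    aa = translate_cds(cds, partial)
    status = "called_partial" if partial or not cds[-3:] in STOP_CODONS else f.raw_status
    if status != f.raw_status:
        f = replace(f, raw_status=status)
    return aa, f


def load_strain(fasta_path, gff3_path, strain_id: str | None = None) -> StrainAnnotation:
    """Read a genome FASTA + GFF3 annotation into a :class:`StrainAnnotation`."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    with open(gff3_path) as fh:
        first = fh.readline()
    if not first.startswith("##gff-version"):
        raise ValueError(f"{gff3_path}: missing ##gff-version pragma")
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    replicon_meta: dict[str, Replicon] = {}
    feats: list[GeneFeature] = []
    for g in db.all_features(order_by=("seqid", "start")):
        if g.seqid not in records:
            raise ValueError(f"{g.id}: seqid {g.seqid} not present in FASTA")
        if g.featuretype == "region":
            replicon_meta[g.seqid] = Replicon(
                name=g.seqid,
                length=len(records[g.seqid]),
                circular=g.attributes.get("Is_circular", ["false"])[0] == "true",
                kind=g.attributes.get("genome", ["chromosome"])[0],
            )
            continue
        if g.featuretype not in ("CDS", "tRNA"):
            continue
        start, end = g.start - 1, g.end  # GFF3 1-based inclusive -> half-open
        if start < 0 or end > len(records[g.seqid]) or start >= end:
            raise ValueError(f"{g.id}: coordinates out of range on {g.seqid}")
        attrs = {k: v[0] for k, v in g.attributes.items()}
        feats.append(GeneFeature(
            id=attrs.get("ID", g.id),
            replicon=g.seqid,
            start=start,
            end=end,
            strand=g.strand if g.strand in "+-" else "+",
            kind=g.featuretype,
            attributes=attrs,
        ))
    replicons = [
        replicon_meta.get(name, Replicon(name=name, length=len(seq)))
        for name, seq in records.items()
    ]
    ann = StrainAnnotation(
        strain_id=strain_id or os.path.basename(str(fasta_path)).split(".")[0],
        replicons=replicons,
        features=feats,
        sequences=records,
    )
    out_feats = []
    for f in ann.features:
        if f.kind == "CDS":
            aa, f = _translate_feature(ann.feature_seq(f), f)
            ann.proteome[f.id] = aa
        out_feats.append(f)
    ann.features = out_feats
    return ann


# ---------------------------------------------------------------------------
# writing


def _gff3_attr(attrs: Mapping[str, str]) -> str:
    def esc(v: str) -> str:
        return v.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")
    return ";".join(f"{k}={esc(str(v))}" for k, v in attrs.items())


def write_strain(ann: StrainAnnotation, fasta_path, gff3_path,
                 protein_path=None) -> None:
    """Write genome FASTA, GFF3 and (optionally) the protein FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in ann.sequences.items()]
    SeqIO.write(recs, str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in ann.replicons:
            fh.write(f"##sequence-region {r.name} 1 {r.length}\n")
        for r in ann.replicons:
            attrs = {"ID": r.name, "genome": r.kind,
                     "Is_circular": "true" if r.circular else "false"}
            fh.write("\t".join([
                r.name, "panoen", "region", "1", str(r.length),
                ".", "+", ".", _gff3_attr(attrs)]) + "\n")
        for f in ann.features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f.id)
            attrs.setdefault("locus_tag", f.id)
            fh.write("\t".join([
                f.replicon, "panoen", f.kind,
                str(f.start + 1), str(f.end), ".", f.strand,
                "0" if f.kind == "CDS" else ".",
                _gff3_attr(attrs)]) + "\n")
    if protein_path is not None:
        write_proteome(ann.proteome, protein_path)


def write_proteome(proteome: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(aa), id=pid, description="") for pid, aa in proteome.items()]
    SeqIO.write(recs, str(path), "fasta")


def load_proteome(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# naive ORF calling (annotation-free plumbing, not a gene finder)


def _orfs_on_strand(seq: str, min_len_codons: int):
    """Yield (start, end) of start->stop ORFs on the forward frame of seq."""
    n = len(seq)
    for frame in range(3):
        prev_stop = frame  # scan from the frame origin
        pos = frame
        pending_start = None
        while pos + 3 <= n:
            codon = seq[pos:pos + 3]
            if pending_start is None and codon in START_CODONS:
                pending_start = pos
            if codon in STOP_CODONS:
                if pending_start is not None:
                    length = (pos + 3 - pending_start) // 3
                    if length >= min_len_codons:
                        yield pending_start, pos + 3
                pending_start = None
            pos += 3


def naive_orf_call(sequences: Mapping[str, str], min_len: int = 30) -> list[GeneFeature]:
    """Greedy longest non-overlapping start->stop ORFs on both strands.

    Ties in length break to the smaller genomic coordinate, then to the
    forward strand.  Returns features named ``orf_<replicon>_<n>``.
    """
    out: list[GeneFeature] = []
    for name in sequences:
        seq = sequences[name].upper()
        n = len(seq)
        cands: list[tuple[int, int, str]] = []
        for s, e in _orfs_on_strand(seq, min_len):
            cands.append((s, e, "+"))
        rc = str(Seq(seq).reverse_complement())
        for s, e in _orfs_on_strand(rc, min_len):
            cands.append((n - e, n - s, "-"))
        cands.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
        taken: list[tuple[int, int]] = []
        chosen = []
        for s, e, strand in cands:
            if any(s < te and ts < e for ts, te in taken):
                continue
            taken.append((s, e))
            chosen.append((s, e, strand))
        chosen.sort()
        for i, (s, e, strand) in enumerate(chosen):
            out.append(GeneFeature(
                id=f"orf_{name}_{i:05d}", replicon=name, start=s, end=e,
                strand=strand, kind="CDS",
            ))
    return out


def write_features_gff3(features: Iterable[GeneFeature],
                        sequences: Mapping[str, str], path) -> None:
    """Write bare features (e.g. ORF calls) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in sequences.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for f in features:
            fh.write("\t".join([
                f.replicon, "panoen", f.kind, str(f.start + 1), str(f.end),
                ".", f.strand, "0" if f.kind == "CDS" else ".",
                _gff3_attr({"ID": f.id})]) + "\n")
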