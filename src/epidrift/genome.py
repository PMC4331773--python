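"""Artificial genome (AG) construction and annotation.

The simulator does not operate on real DNA.  It uses an *artificial genome*:
a long string over the digit alphabet ``0123`` in which genes are discovered
by scanning for a fixed promoter motif.  Each motif occurrence opens a gene
whose length is sampled from a bounded distribution and truncated at the next
motif occurrence, so genes never overlap by construction.

Annotation attaches three things to every gene:

* ``n_h`` — the number of cooperatively acting nucleosomes, one per 200 bases
  of gene length (``n_h = length // 200``).  Genes shorter than 200 bases
  carry no nucleosomes and form the C3 class.
* ``cpg_positions`` — occurrences of a two-digit CpG-analog motif inside the
  gene's regulatory region (taken to be the gene's own interval).
* ``interactions`` — a signed, weighted transcription-factor network: gene j
  regulates gene i when the complement-transform of a fixed-length prefix of
  gene j (its "TF motif") matches a site in gene i's region within an allowed
  number of mismatches.

All coordinates are 0-based, half-open.  Everything is a pure function of
(sequence, motifs, rule), so annotations are recomputable from the sequence
alone, and a fixed seed yields a byte-identical genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

ALPHABET = "0123"

#: default motifs / rule parameters
PROMOTER_MOTIF = "010101"
CPG_MOTIF = "23"
DEFAULT_GENE_LENGTH_RANGE = (50, 2000)
BASES_PER_NUCLEOSOME = 200

Sign = Literal["activating", "repressing"]


@dataclass(frozen=True)
class Interaction:
    """A directed TF interaction ``regulator -> target``."""

    regulator: int
    sign: Sign
    weight: int

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("interaction weight must be non-negative")


@dataclass
class Gene:
    """One gene of the artificial genome (0-based, half-open interval)."""

    id: int
    start: int
    length: int
    n_h: int = 0
    cpg_positions: list[int] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)


@dataclass
class TFMatchRule:
    """How a regulator's TF motif is derived and matched.

    The TF encoded by a gene is represented by the digit-complement
    (``d -> 3 - d``) of the gene's first ``prefix_length`` bases.  A binding
    site is any position in the target gene's region where that motif matches
    with at most ``max_mismatches`` mismatching digits.  The digit immediately
    following the site decides the sign of the interaction: even digits give
    activation, odd digits repression.  Sites whose following digit would fall
    outside the gene region are ignored.
    """

    prefix_length: int = 8
    max_mismatches: int = 1


@dataclass
class Genome:
    """An annotated artificial genome."""

    sequence: str
    genes: list[Gene]
    seed: int | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -1
        for g in sorted(self.genes, key=lambda g: g.start):
            if g.start < 0 or g.end > len(self.sequence):
                raise ValueError(f"gene {g.id} outside sequence bounds")
            if g.start < prev_end:
                raise ValueError(f"gene {g.id} overlaps the previous gene")
            prev_end = g.end
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError("genes must be ordered by start position")

    def gene_sequence(self, gene: Gene) -> str:
        return self.sequence[gene.start : gene.end]


class EmptyGenomeError(ValueError):
    """Raised when promoter scanning discovers no genes at all."""


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _find_motif(seq: str, motif: str, start: int = 0, end: int | None = None) -> list[int]:
    """All (possibly overlapping) occurrences of ``motif`` in ``seq[start:end]``.

    Positions are relative to ``start``.
    """
    end = len(seq) if end is None else end
    out = []
    i = seq.find(motif, start, end)
    while i != -1:
        out.append(i - start)
        i = seq.find(motif, i + 1, end)
    return out


def generate_genome(
    length: int = 400_000,
    promoter_motif: str = PROMOTER_MOTIF,
    gene_length_range: tuple[int, int] = DEFAULT_GENE_LENGTH_RANGE,
    seed: int = 0,
    cpg_motif: str = CPG_MOTIF,
    match_rule: TFMatchRule | None = None,
    annotate: bool = True,
) -> Genome:
    """Generate a random artificial genome and (optionally) annotate it.

    An i.i.d. uniform digit string of the given length is scanned for
    ``promoter_motif``; each occurrence opens a gene whose length is drawn
    uniformly from ``gene_length_range`` and truncated at the next motif
    occurrence and at the sequence end.

    Raises
    ------
    EmptyGenomeError
        If no promoter motif occurs in the sampled sequence.
    """
    lo, hi = gene_length_range
    if length < 10 * (lo + hi) // 2:
        raise ValueError("sequence length must be at least 10x the mean gene length")
    if len(promoter_motif) < 2:
        raise ValueError("promoter motif must have length >= 2")
    rng = np.random.default_rng(seed)
    digits = rng.integers(0, 4, size=length)
    sequence = "".join(ALPHABET[d] for d in digits)

    starts = _find_motif(sequence, promoter_motif)
    if not starts:
        raise EmptyGenomeError(
            f"no occurrence of promoter motif {promoter_motif!r} in the sampled sequence"
        )
    genes: list[Gene] = []
    for k, s in enumerate(starts):
        sampled = int(rng.integers(lo, hi + 1))
        limit = starts[k + 1] - s if k + 1 < len(starts) else length - s
        glen = min(sampled, limit)
        genes.append(Gene(id=k, start=s, length=glen, n_h=glen // BASES_PER_NUCLEOSOME))
    genome = Genome(sequence=sequence, genes=genes, seed=seed)
    if annotate:
        genome = annotate_cpgs(genome, cpg_motif)
        genome = build_tf_network(genome, match_rule or TFMatchRule())
    return genome


def annotate_cpgs(genome: Genome, cpg_motif: str = CPG_MOTIF) -> Genome:
    """Record all occurrences of the CpG-analog motif in each gene's region.

    Positions are relative to the gene start.  Genes may legitimately end up
    with zero CpGs (a subgroup of the short C3 genes does).
    """
    if len(cpg_motif) != 2:
        raise ValueError("CpG motif must have length 2")
    genes = [
        replace(g, cpg_positions=_find_motif(genome.sequence, cpg_motif, g.start, g.end))
        for g in genome.genes
    ]
    return Genome(sequence=genome.sequence, genes=genes, seed=genome.seed)


def tf_motif(gene_seq: str, rule: TFMatchRule) -> str | None:
    """The binding motif of the TF encoded by a gene (None if gene too short)."""
    if len(gene_seq) < rule.prefix_length:
        return None
    prefix = gene_seq[: rule.prefix_length]
    return "".join(ALPHABET[3 - int(c)] for c in prefix)


def find_binding_sites(
    region: str, motif: str, max_mismatches: int
) -> list[tuple[int, Sign]]:
    """Scan a region for motif matches (with mismatches) and their signs.

    A site at position p requires ``region[p + len(motif)]`` to exist; that
    following digit's parity sets the sign (even = activating).
    """
    k = len(motif)
    sites: list[tuple[int, Sign]] = []
    for p in range(len(region) - k):
        mism = sum(a != b for a, b in zip(region[p : p + k], motif))
        if mism <= max_mismatches:
            sign: Sign = (
                "activating" if int(region[p + k]) % 2 == 0 else "repressing"
            )
            sites.append((p, sign))
    return sites


def build_tf_network(genome: Genome, match_rule: TFMatchRule | None = None) -> Genome:
    """Derive the signed, weighted TF-interaction lists for all genes.

    For every ordered pair (j -> i), gene j's TF motif is matched against gene
    i's regulatory region; one interaction per sign is recorded with weight =
    number of sites of that sign.  The scan is vectorized (sliding-window
    mismatch counting); :func:`find_binding_sites` is the plain reference
    implementation of the same rule.
    """
    rule = match_rule or TFMatchRule()
    motifs = [tf_motif(genome.gene_sequence(g), rule) for g in genome.genes]
    motif_arrays = [
        None if m is None else np.frombuffer(m.encode(), dtype=np.uint8) for m in motifs
    ]
    seq_arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    k = rule.prefix_length
    genes: list[Gene] = []
    for gi in genome.genes:
        region = seq_arr[gi.start : gi.end]
        inter: list[Interaction] = []
        if len(region) > k:
            windows = np.lib.stride_tricks.sliding_window_view(region, k)[:-1]
            following_even = (region[k:] - ord("0")) % 2 == 0
            for gj, marr in zip(genome.genes, motif_arrays):
                if marr is None:
                    continue
                hits = (windows != marr).sum(axis=1) <= rule.max_mismatches
                n_act = int(np.sum(hits & following_even))
                n_rep = int(np.sum(hits & ~following_even))
                if n_act:
                    inter.append(
                        Interaction(regulator=gj.id, sign="activating", weight=n_act)
                    )
                if n_rep:
                    inter.append(
                        Interaction(regulator=gj.id, sign="repressing", weight=n_rep)
                    )
        genes.append(replace(gi, interactions=inter))
    return Genome(sequence=genome.sequence, genes=genes, seed=genome.seed)


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------


def make_fixture_genome(
    n_h: Sequence[int],
    n_cpg: Sequence[int] | None = None,
    seed: int = 0,
    cpg_motif: str = CPG_MOTIF,
    spacer: int = 10,
    match_rule: TFMatchRule | None = None,
) -> Genome:
    """Construct a small deterministic genome with prescribed annotations.

    Every layer of the model is testable on these fixtures without any
    download or large random genome.  ``n_h[k]`` prescribes the nucleosome
    count of gene k (gene length = ``200 * n_h`` or 150 for ``n_h == 0``);
    ``n_cpg[k]`` prescribes its exact CpG count (default: ``2 * n_h + 2``, and
    0 for every second nucleosome-free gene so that the no-CpG C3 subgroup is
    populated).

    Gene bodies are built from digits ``{0, 1}`` with CpG motifs planted at
    fixed spacing, so the requested counts are exact by construction and the
    annotation scan provably recovers them.
    """
    if n_cpg is None:
        c3_seen = 0
        n_cpg = []
        for h in n_h:
            if h == 0:
                n_cpg.append(0 if c3_seen % 2 == 0 else 2)
                c3_seen += 1
            else:
                n_cpg.append(2 * h + 2)
    if len(n_cpg) != len(n_h):
        raise ValueError("n_cpg and n_h must have equal length")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for k, (h, c) in enumerate(zip(n_h, n_cpg)):
        length = BASES_PER_NUCLEOSOME * h if h > 0 else 150
        if length < 3 * c:
            raise ValueError(f"gene {k}: {c} CpGs do not fit in {length} bases")
        body = list(ALPHABET[d] for d in rng.integers(0, 2, size=length))
        cpg_positions = []
        for m in range(c):
            p = 3 * m  # non-adjacent planting; no accidental occurrences
            body[p : p + 2] = list(cpg_motif)
            cpg_positions.append(p)
        parts.append("".join(body))
        parts.append("".join(ALPHABET[d] for d in rng.integers(0, 2, size=spacer)))
        genes.append(
            Gene(id=k, start=pos, length=length, n_h=h, cpg_positions=cpg_positions)
        )
        pos += length + spacer
    genome = Genome(sequence="".join(parts), genes=genes, seed=seed)
    return build_tf_network(genome, match_rule or TFMatchRule())


# ---------------------------------------------------------------------------
# serialization: FASTA-like sequence + GFF3-style annotation
# ---------------------------------------------------------------------------

_SEQID = "AG1"


def write_genome(genome: Genome, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write the digit sequence (FASTA-like) and annotations (GFF3-style).

    GFF3 columns are 1-based closed intervals as usual; CpG positions and
    interactions are carried in the attribute column.  The pair of files
    round-trips losslessly through :func:`read_genome`.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    with fasta_path.open("w") as fh:
        seed = "" if genome.seed is None else f" seed={genome.seed}"
        fh.write(f">{_SEQID}{seed}\n")
        for i in range(0, len(genome.sequence), 80):
            fh.write(genome.sequence[i : i + 80] + "\n")
    with gff_path.open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {_SEQID} 1 {len(genome.sequence)}\n")
        for g in genome.genes:
            attrs = [f"ID=gene{g.id}", f"nh={g.n_h}"]
            if g.cpg_positions:
                attrs.append("cpgs=" + ",".join(map(str, g.cpg_positions)))
            if g.interactions:
                enc = ",".join(
                    f"{i.regulator}:{'+' if i.sign == 'activating' else '-'}:{i.weight}"
                    for i in g.interactions
                )
                attrs.append("interactions=" + enc)
            fh.write(
                "\t".join(
                    [
                        _SEQID,
                        "epidrift",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        "+",
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_genome(fasta_path: str | Path, gff_path: str | Path) -> Genome:
    """Read a genome written by :func:`write_genome`."""
    seq_lines: list[str] = []
    seed: int | None = None
    with Path(fasta_path).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                for tok in line[1:].split():
                    if tok.startswith("seed="):
                        seed = int(tok[5:])
            elif line:
                seq_lines.append(line)
    sequence = "".join(seq_lines)

    genes: list[Gene] = []
    with Path(gff_path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            start1, end1 = int(cols[3]), int(cols[4])
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
            gid = int(attrs["ID"].removeprefix("gene"))
            cpgs = (
                [int(x) for x in attrs["cpgs"].split(",")] if "cpgs" in attrs else []
            )
            inter = []
            if "interactions" in attrs:
                for tok in attrs["interactions"].split(","):
                    reg, sgn, w = tok.split(":")
                    inter.append(
                        Interaction(
                            regulator=int(reg),
                            sign="activating" if sgn == "+" else "repressing",
                            weight=int(w),
                        )
                    )
            genes.append(
                Gene(
                    id=gid,
                    start=start1 - 1,
                    length=end1 - start1 + 1,
                    n_h=int(attrs["nh"]),
                    cpg_positions=cpgs,
                    interactions=inter,
                )
            )
    genes.sort(key=lambda g: g.start)
    return Genome(sequence=sequence, genes=genes, seed=seed)
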