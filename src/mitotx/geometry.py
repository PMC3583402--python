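"""Circular genome geometry: genes, promoters, protein terminator sites.

Animal mitochondrial DNA is a circle of 15-18 kbp with genes on both
strands.  Transcription initiates at a handful of promoters (HSP* on the
heavy strand, LSP* on the light strand) and phage-type polymerases then
elongate around the circle.  This module defines the in-memory geometry,
its validation, readers for GenBank / GFF3 / a plain TSV dialect, and a
toy-genome generator used throughout the test-suite.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open and circular (arithmetic
modulo ``length``).  External formats (GenBank, GFF3, the TSV dialect)
use 1-based inclusive coordinates and are converted on the way in/out.
Heavy-strand transcription moves toward increasing coordinates, light-
strand transcription toward decreasing coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from . import _circular as circ

HEAVY = "heavy"
LIGHT = "light"
STRANDS = (HEAVY, LIGHT)

#: occupancy of the phage-type polymerase relative to its active position,
#: in transcription direction: -15..+1 inclusive (17 nt).
FOOTPRINT_REL = (-15, 1)
FOOTPRINT_NT = FOOTPRINT_REL[1] - FOOTPRINT_REL[0] + 1

#: default width of the mTERF protein binding region (bp)
FACTOR_SITE_NT = 28


def strand_direction(strand: str) -> int:
    if strand == HEAVY:
        return 1
    if strand == LIGHT:
        return -1
    raise ValueError(f"unknown strand {strand!r} (expected 'heavy' or 'light')")


def _directional_arc(pos: int, rel_lo: int, rel_hi: int, strand: str, L: int):
    """Absolute circular arc of [rel_lo, rel_hi] around ``pos`` measured in
    transcription direction."""
    d = strand_direction(strand)
    length = rel_hi - rel_lo + 1
    start = pos + rel_lo if d > 0 else pos - rel_hi
    return circ.arc(start, length, L)


@dataclass(frozen=True)
class Gene:
    name: str
    start: int          # 0-based, inclusive
    end: int            # 0-based, exclusive; may be < start for origin-spanning genes
    strand: str

    def length_on(self, L: int) -> int:
        return (self.end - self.start) % L or L

    def arc(self, L: int):
        return circ.arc(self.start, self.length_on(L), L)


@dataclass(frozen=True)
class Promoter:
    """A promoter with its transcription start site and exclusion footprint.

    The footprint is the region that must be completely free of polymerases
    and bound factors for a binding attempt to succeed; by default it spans
    -15..+1 around the TSS in transcription direction (17 nt).
    """

    name: str
    tss: int            # 0-based
    strand: str
    footprint_rel: tuple[int, int] = FOOTPRINT_REL

    def __post_init__(self):
        lo, hi = self.footprint_rel
        if not (lo <= 0 <= hi):
            raise ValueError(f"promoter {self.name}: TSS must lie inside footprint")

    def footprint_arc(self, L: int):
        lo, hi = self.footprint_rel
        return _directional_arc(self.tss, lo, hi, self.strand, L)

    @property
    def direction(self) -> int:
        return strand_direction(self.strand)


@dataclass(frozen=True)
class FactorSite:
    """Binding region of a site-specific DNA-binding protein (mTERF).

    A bound site acts as a polarized terminator: a polymerase reaching it
    passes with probability ``pass_prob_heavy`` (heavy strand) or
    ``pass_prob_light`` (light strand), dissociating the complex; otherwise
    it terminates and the complex survives.  ``binding_intensity`` is the
    Poisson rate of binding attempts (per second); spontaneous dissociation
    is folded into this intensity and is not a separate event.
    """

    name: str
    start: int          # 0-based inclusive
    end: int            # 0-based exclusive (start + width, modulo length)
    pass_prob_heavy: float = 1.0
    pass_prob_light: float = 1.0
    binding_intensity: float = 0.0

    def __post_init__(self):
        for v, what in ((self.pass_prob_heavy, "pass_prob_heavy"),
                        (self.pass_prob_light, "pass_prob_light")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"factor site {self.name}: {what}={v} outside [0,1]")
        if self.binding_intensity < 0:
            raise ValueError(f"factor site {self.name}: negative binding intensity")

    def length_on(self, L: int) -> int:
        return (self.end - self.start) % L or L

    def arc(self, L: int):
        return circ.arc(self.start, self.length_on(L), L)


@dataclass(frozen=True)
class QuadruplexSite:
    """A protein-independent (G-quadruplex) terminator.

    Each polymerase passing on ``strand`` terminates independently with
    ``termination_prob``.  The default probability is 0 everywhere; a
    non-zero value must be supplied by the user.
    """

    name: str
    start: int
    end: int
    strand: str
    termination_prob: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.termination_prob <= 1.0:
            raise ValueError(f"quadruplex {self.name}: probability outside [0,1]")

    def length_on(self, L: int) -> int:
        return (self.end - self.start) % L or L

    def arc(self, L: int):
        return circ.arc(self.start, self.length_on(L), L)


@dataclass
class GenomeGeometry:
    """A validated circular chromosome layout."""

    length: int
    genes: list[Gene] = field(default_factory=list)
    promoters: list[Promoter] = field(default_factory=list)
    factor_sites: list[FactorSite] = field(default_factory=list)
    quadruplex_sites: list[QuadruplexSite] = field(default_factory=list)
    circular: bool = True
    name: str = ""

    def __post_init__(self):
        self.normalize()
        self.validate()

    # -- validation ---------------------------------------------------
    def normalize(self) -> "GenomeGeometry":
        """Fold all coordinates into [0, length).  Idempotent."""
        L = self.length
        self.genes = [replace(g, start=g.start % L, end=g.end % L) for g in self.genes]
        self.promoters = [replace(p, tss=p.tss % L) for p in self.promoters]
        self.factor_sites = [replace(s, start=s.start % L, end=s.end % L)
                             for s in self.factor_sites]
        self.quadruplex_sites = [replace(s, start=s.start % L, end=s.end % L)
                                 for s in self.quadruplex_sites]
        return self

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not self.circular:
            raise ValueError("only circular chromosomes are supported")
        for g in self.genes:
            if g.strand not in STRANDS:
                raise ValueError(f"gene {g.name}: bad strand {g.strand!r}")
        for p in self.promoters:
            strand_direction(p.strand)
        seen = set()
        for p in self.promoters:
            key = (p.tss, p.strand)
            if key in seen:
                raise ValueError(f"duplicate promoter at TSS {p.tss} on {p.strand}")
            seen.add(key)
        names = [p.name for p in self.promoters]
        if len(names) != len(set(names)):
            raise ValueError("promoter names must be unique")

    # -- lookup helpers ------------------------------------------------
    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def promoter(self, name: str) -> Promoter:
        for p in self.promoters:
            if p.name == name:
                return p
        raise KeyError(name)

    def factor_site(self, name: str) -> FactorSite:
        for s in self.factor_sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def __eq__(self, other):
        if not isinstance(other, GenomeGeometry):
            return NotImplemented
        return (self.length == other.length and self.circular == other.circular
                and self.genes == other.genes and self.promoters == other.promoters
                and self.factor_sites == other.factor_sites
                and self.quadruplex_sites == other.quadruplex_sites)


# ----------------------------------------------------------------------
# TSV geometry dialect
#
# Header:   #length=<N> circular=1
# Rows:     feature_type <TAB> name <TAB> start <TAB> end <TAB> strand <TAB> extra
# with 1-based inclusive coordinates; promoter rows use start=end=TSS;
# extra is ';'-separated key=value pairs.
# ----------------------------------------------------------------------

class GeometryFormatError(ValueError):
    """Raised when a geometry file cannot be parsed."""


def _parse_extra(extra: str) -> dict[str, str]:
    out = {}
    for chunk in extra.strip().split(";"):
        if chunk and "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _fmt_extra(d: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in d.items())


def write_geometry_tsv(geom: GenomeGeometry, path_or_buf) -> None:
    """Write a geometry in the package's TSV dialect (1-based inclusive)."""
    L = geom.length
    lines = [f"#length={L} circular={1 if geom.circular else 0}"
             + (f" name={geom.name}" if geom.name else "")]
    for g in geom.genes:
        end_incl = (g.end - 1) % L
        lines.append(f"gene\t{g.name}\t{g.start + 1}\t{end_incl + 1}\t{g.strand}\t")
    for p in geom.promoters:
        extra = {}
        if p.footprint_rel != FOOTPRINT_REL:
            extra["footprint"] = f"{p.footprint_rel[0]}..{p.footprint_rel[1]}"
        lines.append(f"promoter\t{p.name}\t{p.tss + 1}\t{p.tss + 1}\t{p.strand}\t"
                     + _fmt_extra(extra))
    for s in geom.factor_sites:
        end_incl = (s.end - 1) % L
        extra = {"p": repr(s.pass_prob_heavy), "q": repr(s.pass_prob_light),
                 "intensity": repr(s.binding_intensity)}
        lines.append(f"factor_site\t{s.name}\t{s.start + 1}\t{end_incl + 1}\t.\t"
                     + _fmt_extra(extra))
    for s in geom.quadruplex_sites:
        end_incl = (s.end - 1) % L
        extra = {"tprob": repr(s.termination_prob)}
        lines.append(f"quadruplex\t{s.name}\t{s.start + 1}\t{end_incl + 1}\t{s.strand}\t"
                     + _fmt_extra(extra))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def _read_geometry_tsv(lines, source="<tsv>") -> GenomeGeometry:
    length = None
    circular = True
    name = ""
    genes, promoters, sites, quads = [], [], [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            for tok in line.lstrip("#").split():
                if tok.startswith("length="):
                    length = int(tok.split("=", 1)[1])
                elif tok.startswith("circular="):
                    circular = tok.split("=", 1)[1] not in ("0", "false")
                elif tok.startswith("name="):
                    name = tok.split("=", 1)[1]
            continue
        if length is None:
            raise GeometryFormatError(f"{source}:{lineno}: feature row before #length header")
        parts = line.split("\t")
        if len(parts) < 5:
            raise GeometryFormatError(f"{source}:{lineno}: expected >=5 tab-separated fields")
        ftype, fname, s_start, s_end, strand = parts[:5]
        extra = _parse_extra(parts[5]) if len(parts) > 5 else {}
        try:
            start1, end1 = int(s_start), int(s_end)
        except ValueError as exc:
            raise GeometryFormatError(f"{source}:{lineno}: bad coordinate: {exc}") from None
        for c in (start1, end1):
            if not 1 <= c <= length:
                raise GeometryFormatError(
                    f"{source}:{lineno}: coordinate {c} outside [1, {length}]")
        start0, end0 = start1 - 1, end1 % length  # 1-based incl -> 0-based half-open
        if ftype == "gene":
            genes.append(Gene(fname, start0, end0, strand))
        elif ftype == "promoter":
            fp = FOOTPRINT_REL
            if "footprint" in extra:
                lo, hi = extra["footprint"].split("..")
                fp = (int(lo), int(hi))
            promoters.append(Promoter(fname, start0, strand, fp))
        elif ftype == "factor_site":
            sites.append(FactorSite(
                fname, start0, end0,
                pass_prob_heavy=float(extra.get("p", 1.0)),
                pass_prob_light=float(extra.get("q", 1.0)),
                binding_intensity=float(extra.get("intensity", 0.0))))
        elif ftype == "quadruplex":
            quads.append(QuadruplexSite(fname, start0, end0, strand,
                                        float(extra.get("tprob", 0.0))))
        else:
            raise GeometryFormatError(f"{source}:{lineno}: unknown feature type {ftype!r}")
    if length is None:
        raise GeometryFormatError(f"{source}: missing '#length=' header")
    return GenomeGeometry(length, genes, promoters, sites, quads, circular, name)


def _load_genbank(path) -> GenomeGeometry:
    from Bio import SeqIO
    record = SeqIO.read(path, "genbank")
    L = len(record.seq)
    genes = []
    preferred = {"gene"}
    fallback = {"CDS", "tRNA", "rRNA"}
    have_gene_feats = any(f.type in preferred for f in record.features)
    take = preferred if have_gene_feats else fallback
    for f in record.features:
        if f.type not in take:
            continue
        quals = f.qualifiers
        fname = (quals.get("gene") or quals.get("product") or
                 quals.get("locus_tag") or ["?"])[0]
        strand = HEAVY if (f.location.strand or 1) >= 0 else LIGHT
        genes.append(Gene(fname, int(f.location.start), int(f.location.end) % L, strand))
    return GenomeGeometry(L, genes, name=record.id)


def _load_gff3(path, length: int | None = None) -> GenomeGeometry:
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    if length is None:
        directives = [d for d in db.directives if d.startswith("sequence-region")]
        if not directives:
            raise GeometryFormatError(
                "GFF3 lacks ##sequence-region directive; pass length= explicitly")
        length = int(directives[0].split()[-1])
    genes = []
    for f in db.features_of_type("gene"):
        fname = f.attributes.get("Name", f.attributes.get("ID", ["?"]))[0]
        strand = LIGHT if f.strand == "-" else HEAVY
        genes.append(Gene(fname, f.start - 1, f.end % length, strand))
    return GenomeGeometry(length, genes)


def load_geometry(path, format: str = "tsv", **kwargs) -> GenomeGeometry:
    """Load a circular genome geometry from ``tsv``, ``genbank`` or ``gff3``.

    GenBank and GFF3 carry genes only; promoters, factor sites and
    quadruplexes are always supplied through the TSV dialect (or built
    programmatically) and can be merged with :func:`merge_overlay`.
    """
    if format == "tsv":
        if hasattr(path, "read"):
            return _read_geometry_tsv(path, source="<buffer>")
        with open(path) as fh:
            return _read_geometry_tsv(fh, source=str(path))
    if format == "genbank":
        return _load_genbank(path)
    if format == "gff3":
        return _load_gff3(path, kwargs.get("length"))
    raise ValueError(f"unknown geometry format {format!r}")


def loads_geometry(text: str) -> GenomeGeometry:
    return _read_geometry_tsv(io.StringIO(text))


def dumps_geometry(geom: GenomeGeometry) -> str:
    buf = io.StringIO()
    write_geometry_tsv(geom, buf)
    return buf.getvalue()


def merge_overlay(base: GenomeGeometry, overlay: GenomeGeometry) -> GenomeGeometry:
    """Overlay promoters/factor sites/quadruplexes onto a gene-only geometry."""
    if overlay.length != base.length:
        raise ValueError("overlay length differs from base geometry")
    return GenomeGeometry(
        base.length,
        genes=base.genes + overlay.genes,
        promoters=base.promoters + overlay.promoters,
        factor_sites=base.factor_sites + overlay.factor_sites,
        quadruplex_sites=base.quadruplex_sites + overlay.quadruplex_sites,
        name=base.name or overlay.name)


def make_toy_genome(length: int,
                    promoter_specs=(),
                    gene_specs=(),
                    factor_specs=(),
                    quadruplex_specs=(),
                    name: str = "toy") -> GenomeGeometry:
    """Deterministically build a small synthetic circular genome.

    Specs are tuples (all 0-based internal coordinates):
      promoters:    (name, tss, strand)
      genes:        (name, start, end, strand)
      factors:      (name, start, [width, p, q, intensity])
      quadruplexes: (name, start, end, strand, termination_prob)

    Overlapping promoter footprints on the same strand are rejected — the
    toy generator is meant to produce unambiguous oracle geometries.
    """
    promoters = [Promoter(n, t, s) for (n, t, s) in promoter_specs]
    genes = [Gene(*gs) for gs in gene_specs]
    sites = []
    for fs in factor_specs:
        fname, start = fs[0], fs[1]
        width = fs[2] if len(fs) > 2 else FACTOR_SITE_NT
        p = fs[3] if len(fs) > 3 else 1.0
        q = fs[4] if len(fs) > 4 else 1.0
        lam = fs[5] if len(fs) > 5 else 0.0
        sites.append(FactorSite(fname, start, (start + width) % length, p, q, lam))
    quads = [QuadruplexSite(*qs) for qs in quadruplex_specs]
    geom = GenomeGeometry(length, genes, promoters, sites, quads, name=name)
    for i, a in enumerate(geom.promoters):
        for b in geom.promoters[i + 1:]:
            if a.strand == b.strand and circ.arcs_overlap(
                    a.footprint_arc(length), b.footprint_arc(length), length):
                raise ValueError(
                    f"promoter footprints of {a.name} and {b.name} overlap on {a.strand}")
    return geom


#: Relative transcription-initiation intensities of the five frog promoters,
#: as fractions of LSP1.
FROG_RELATIVE_INTENSITIES = {
    "HSP1": 0.136,
    "HSP2": 0.600,
    "LSP1": 1.000,
    "LSP2A": 0.166,
    "LSP2B": 0.382,
}


def frog_promoter_intensities(lsp1_intensity: float) -> dict[str, float]:
    """Scale the frog promoter intensity ratios by the LSP1 intensity.

    The five Xenopus promoters have experimentally estimated initiation
    intensities relative to LSP1 (HSP1 13.6%, HSP2 60.0%, LSP1 100%,
    LSP2A 16.6%, LSP2B 38.2%).
    """
    if lsp1_intensity < 0:
        raise ValueError("LSP1 intensity must be non-negative")
    return {k: v * lsp1_intensity for k, v in FROG_RELATIVE_INTENSITIES.items()}
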