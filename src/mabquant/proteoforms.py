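"""Glycan nomenclature, proteoform enumeration, and mass annotation.

An intact IgG carries one N-glycan per heavy chain, so intact-level glycoforms
are *pairs* of glycans.  This module maps Oxford-style glycan names (A2G0F,
M5, A2S1G0F, ...) to monosaccharide compositions, enumerates proteoform
libraries as the cartesian product of glycan pairs x C-terminal lysine
variants x optional modification deltas, and annotates observed (deconvoluted)
masses against the library within a ppm tolerance.

Isobaric glycoform pairs (e.g. A2G1F/A2G1F vs A2G0F/A2G2F) are merged into a
single library entry with a combined label, since no mass-based method can
separate them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .chem import (
    ElementalComposition,
    FormulaError,
    MassValue,
    ModDelta,
    apply_mods,
    mass,
    parse_formula,
    sequence_composition,
)

__all__ = [
    "GlycanComposition",
    "ChainSpec",
    "Proteoform",
    "Annotation",
    "glycan_from_name",
    "build_library",
    "ppm_error",
    "annotate_peaks",
    "rituximab_chains",
    "library_from_definition",
    "export_library_tsv",
]

# Monosaccharide residue compositions (residue = sugar - water).
_SUGARS = {
    "HexNAc": parse_formula("C8H13NO5"),
    "Hex": parse_formula("C6H10O5"),
    "Fuc": parse_formula("C6H10O4"),
    "NeuAc": parse_formula("C11H17NO8"),
}

#: Lysine residue composition; the 0K/1K/2K ladder spacing.
LYS_RESIDUE = parse_formula("C6H12N2O")

#: Default number of inter/intra-chain disulfide bonds for an intact IgG1.
DEFAULT_DISULFIDES = 16


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide residue counts of one N-glycan."""

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self):
        if min(self.hexnac, self.hex, self.fuc, self.neuac) < 0:
            raise ValueError("negative monosaccharide count")

    def composition(self) -> ElementalComposition:
        return (
            self.hexnac * _SUGARS["HexNAc"]
            + self.hex * _SUGARS["Hex"]
            + self.fuc * _SUGARS["Fuc"]
            + self.neuac * _SUGARS["NeuAc"]
        )

    def mass(self) -> MassValue:
        return mass(self.composition())

    def counts(self) -> tuple[int, int, int, int]:
        return (self.hexnac, self.hex, self.fuc, self.neuac)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.fuc + other.fuc,
            self.neuac + other.neuac,
        )


_OXFORD = re.compile(r"^A(?P<ant>[12])(?:S(?P<s>[12]))?G(?P<g>[0-2])(?P<f>F)?$")
_MANNOSE = re.compile(r"^M(?P<m>[5-9])$")


def glycan_from_name(
    name: str, registry: Mapping[str, GlycanComposition] | None = None
) -> GlycanComposition:
    """Map an Oxford-style glycan label to its monosaccharide composition.

    Supported grammar: ``A{1,2}[S{1,2}]G{0..2}[F]`` (complex bi/monoantennary,
    optionally sialylated and core-fucosylated) and ``M{5..9}`` (oligomannose).
    ``registry`` lets callers register arbitrary label -> composition pairs
    (checked first), e.g. for appendix-style single-letter minor variants.

    Composition rules: the complex-type core is HexNAc2Hex3 plus one HexNAc
    per antenna; each galactose (G) and each sialic-acid cap (S, which sits on
    its own galactose) adds one Hex; S adds one NeuAc; F adds one core Fuc.
    """
    if registry and name in registry:
        return registry[name]
    m = _MANNOSE.match(name)
    if m:
        return GlycanComposition(hexnac=2, hex=int(m.group("m")))
    m = _OXFORD.match(name)
    if m:
        antennae = int(m.group("ant"))
        sial = int(m.group("s") or 0)
        gal = int(m.group("g"))
        return GlycanComposition(
            hexnac=2 + antennae,
            hex=3 + gal + sial,
            fuc=1 if m.group("f") else 0,
            neuac=sial,
        )
    raise FormulaError(f"unparseable glycan name {name!r}")


@dataclass(frozen=True)
class ChainSpec:
    """One polypeptide chain of the assembly: sequence, copy number, mods."""

    name: str
    sequence: str
    copies: int = 1
    mods: tuple[ModDelta, ...] = ()

    def composition(self) -> ElementalComposition:
        one = apply_mods(sequence_composition(self.sequence, water=True), self.mods)
        return one * self.copies


@dataclass(frozen=True)
class Proteoform:
    """A named intact species: chains + glycan pair + variant modifications."""

    label: str
    chains: tuple[ChainSpec, ...]
    glycan_pair: tuple[GlycanComposition, GlycanComposition]
    glycan_labels: tuple[str, ...]
    lysine_count: int
    extra_mods: tuple[ModDelta, ...] = ()
    n_disulfides: int = DEFAULT_DISULFIDES

    def composition(self) -> ElementalComposition:
        comp = ElementalComposition()
        for chain in self.chains:
            comp = comp + chain.composition()
        # each disulfide bond removes two hydrogens
        comp = comp - ElementalComposition({"H": 2 * self.n_disulfides})
        for glycan in self.glycan_pair:
            comp = comp + glycan.composition()
        comp = comp + self.lysine_count * LYS_RESIDUE
        return apply_mods(comp, self.extra_mods)

    @property
    def mass(self) -> MassValue:
        return mass(self.composition())

    def glycan_counts(self) -> tuple[int, int, int, int]:
        """Summed monosaccharide counts of the glycan pair."""
        return (self.glycan_pair[0] + self.glycan_pair[1]).counts()


@dataclass(frozen=True)
class Annotation:
    """Assignment of one observed mass to a library proteoform (or None)."""

    observed: float
    label: str | None
    ppm: float | None


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def _pair_key(ga: GlycanComposition, gb: GlycanComposition) -> tuple:
    # unordered pair identity by total composition: merges mass-isobaric pairs
    return (ga + gb).counts()


def _parse_pair(pair, registry) -> tuple[str, str]:
    if isinstance(pair, str):
        a, b = pair.split("/")
    else:
        a, b = pair
    return a.strip(), b.strip()


def build_library(
    chains: Sequence[ChainSpec],
    glycan_pairs: Sequence,
    lysine_variants: Sequence[int] = (0, 1, 2),
    extra_mods: Sequence[ModDelta] = (),
    n_disulfides: int = DEFAULT_DISULFIDES,
    glycan_registry: Mapping[str, GlycanComposition] | None = None,
) -> list[Proteoform]:
    """Enumerate proteoforms: glycan pairs x lysine variants (+ shared mods).

    ``glycan_pairs`` are ``"X/Y"`` strings or (name, name) tuples; pairs are
    unordered, and pairs whose summed monosaccharide composition coincides
    (isobars such as A2G1F/A2G1F and A2G0F/A2G2F) collapse into one entry with
    a combined label.  The result is sorted by monoisotopic mass.
    """
    if not glycan_pairs:
        raise ValueError("empty glycan pair list")
    # resolve and merge isobaric pairs, preserving first-seen order
    merged: dict[tuple, dict] = {}
    for pair in glycan_pairs:
        a, b = _parse_pair(pair, glycan_registry)
        ga = glycan_from_name(a, glycan_registry)
        gb = glycan_from_name(b, glycan_registry)
        key = _pair_key(ga, gb)
        label = f"{a}/{b}"
        if key in merged:
            merged[key]["labels"].append(label)
        else:
            merged[key] = {"pair": (ga, gb), "labels": [label]}
    out = []
    for entry in merged.values():
        labels = entry["labels"]
        pair_label = labels[0] + ("" if len(labels) == 1 else f" (or {labels[1]})")
        for k in lysine_variants:
            out.append(
                Proteoform(
                    label=f"{k}K {pair_label}",
                    chains=tuple(chains),
                    glycan_pair=entry["pair"],
                    glycan_labels=tuple(labels),
                    lysine_count=k,
                    extra_mods=tuple(extra_mods),
                    n_disulfides=n_disulfides,
                )
            )
    out.sort(key=lambda p: p.mass.mono)
    return out


def annotate_peaks(
    peaks: Sequence[tuple[float, float]],
    library: Sequence[Proteoform],
    tolerance_ppm: float = 20.0,
    which: str = "avg",
) -> list[Annotation]:
    """Assign each observed mass the nearest library mass within tolerance.

    ``which`` selects the mass domain ("avg" for deconvoluted intact spectra,
    where isotopes are unresolved; "mono" otherwise).  Ties are broken by
    smaller absolute ppm error, then by the lighter proteoform.  Unassigned
    peaks come back with ``label=None``.
    """
    masses = [getattr(p.mass, which) for p in library]
    out = []
    for observed, _intensity in peaks:
        best = None
        for theo, prot in sorted(zip(masses, library), key=lambda t: t[0]):
            err = ppm_error(observed, theo)
            if abs(err) <= tolerance_ppm and (best is None or abs(err) < abs(best[0])):
                best = (err, prot.label)
        if best is None:
            out.append(Annotation(observed, None, None))
        else:
            out.append(Annotation(observed, best[1], best[0]))
    return out


def rituximab_chains(strip_hc_lysine: bool = True) -> list[ChainSpec]:
    """The packaged rituximab chain fixture: 2 heavy + 2 light chains.

    The heavy chain is returned lysine-clipped (0K backbone) by default so
    that library lysine counts are absolute.  The FASTA fixture is editable;
    absolute masses depend on it while all delta-mass logic does not.
    """
    path = resources.files("mabquant.data").joinpath("rituximab.fasta")
    chains = []
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            heavy = "heavy" in rec.id
            if heavy and strip_hc_lysine and seq.endswith("K"):
                seq = seq[:-1]
            chains.append(ChainSpec(name=rec.id, sequence=seq, copies=2))
    return chains


def library_from_definition(
    definition: Mapping, base_dir: str = ".", mod_registry: Mapping[str, ModDelta] | None = None
) -> list[Proteoform]:
    """Build a library from a parsed YAML proteoform definition.

    Keys: ``glycan_pairs`` (required), ``lysine_variants``, ``extra_mods``
    (names resolved against the modification registry), ``n_disulfides``,
    ``chains`` (``{fasta: path}``; omitted -> packaged rituximab fixture),
    ``custom_glycans`` (label -> formula-like ``{hexnac, hex, fuc, neuac}``).
    """
    import os

    from .chem import load_mod_registry

    if mod_registry is None:
        mod_registry = load_mod_registry()
    chains_cfg = definition.get("chains")
    if chains_cfg and "fasta" in chains_cfg:
        fasta = os.path.join(base_dir, chains_cfg["fasta"])
        chains = []
        for rec in SeqIO.parse(fasta, "fasta"):
            seq = str(rec.seq)
            if "heavy" in rec.id and chains_cfg.get("strip_hc_lysine", True) and seq.endswith("K"):
                seq = seq[:-1]
            chains.append(ChainSpec(name=rec.id, sequence=seq, copies=2))
    else:
        chains = rituximab_chains()
    registry = {
        label: GlycanComposition(**{k.lower(): v for k, v in counts.items()})
        for label, counts in (definition.get("custom_glycans") or {}).items()
    }
    extra = tuple(mod_registry[name] for name in definition.get("extra_mods", []))
    return build_library(
        chains,
        definition["glycan_pairs"],
        lysine_variants=definition.get("lysine_variants", (0, 1, 2)),
        extra_mods=extra,
        n_disulfides=definition.get("n_disulfides", DEFAULT_DISULFIDES),
        glycan_registry=registry,
    )


def export_library_tsv(library: Iterable[Proteoform], path: str) -> None:
    """Write the library as TSV: label, composition, mono mass, avg mass."""
    with open(path, "w") as fh:
        fh.write("label\tcomposition\tmono_mass\tavg_mass\n")
        for p in library:
            mv = p.mass
            fh.write(f"{p.label}\t{p.composition().to_string()}\t{mv.mono:.4f}\t{mv.avg:.4f}\n")
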