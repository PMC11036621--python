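"""Synthetic GenBank-format organelle genomes with known name variants.

Real synonym harvesting runs over tens of thousands of deposited genomes;
the generator here stands in for such a corpus at desk scale.  Each
synthetic genome carries one feature per canonical marker of the chosen
organelle (CDS for protein-coding markers, rRNA for ribosomal ones, and a
D-loop feature on mitochondrial genomes), with product names drawn from the
packaged long-name lexicon and then perturbed the way depositor annotations
actually vary: case changes, hyphen/space swaps, and rare single-character
typos of the kind seen in public records ("cytchrome", "cutochrome").
One decoy tRNA per genome checks that non-target features stay excluded.

Every planted spelling is recorded in a ground-truth map, so a database
build over the corpus can be scored exactly.  Generation is fully
deterministic for a given (n, organelle, seed, rates) tuple.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass
from pathlib import Path
from random import Random
from typing import Dict, List, Optional, Tuple, Union

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .normalize import ORGANELLES, canonicalize_text
from .store import SynonymTable, load_seed_table

__all__ = [
    "PerturbationParams",
    "FixtureTruth",
    "generate_corpus",
]

_RRNA_MARKERS = {"12S", "16S", "rrn16S", "rrn23S", "rrn4.5S", "rrn5S"}
_FEATURE_SPAN = 60  # bp per synthetic feature


@dataclass(frozen=True)
class PerturbationParams:
    """Rates of the three annotation-noise processes.

    ``case_flip_rate`` — per-name probability of re-casing the whole name
    (upper/title/lower); ``hyphenation_rate`` — per-separator probability
    of swapping a space for a hyphen or vice versa; ``typo_rate`` —
    per-character probability of a substitution/deletion/insertion typo.
    Defaults reflect the mild noise of curated genome annotations.
    """

    case_flip_rate: float = 0.1
    hyphenation_rate: float = 0.1
    typo_rate: float = 0.02

    def validate(self) -> None:
        for name, rate in asdict(self).items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass
class FixtureTruth:
    """Ground truth emitted beside a synthetic corpus.

    ``mapping`` holds every planted spelling (gene qualifiers and
    perturbed product names alike) keyed by the raw string, with its
    canonical short name as value; all pairs belong to ``organelle``.
    """

    mapping: Dict[str, str]
    organelle: str
    seed: int
    params: PerturbationParams

    def normalized_mapping(self) -> Dict[str, str]:
        """Mapping keyed by normalized variant, as a lookup table sees it."""
        return {canonicalize_text(v): s for v, s in self.mapping.items()}

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        doc = {
            "organelle": self.organelle,
            "seed": self.seed,
            "params": asdict(self.params),
            "mapping": self.mapping,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, ensure_ascii=False, indent=1, sort_keys=True)
            fh.write("\n")
        return path


def _perturb_case(name: str, rng: Random) -> str:
    style = rng.choice(("upper", "title", "lower"))
    if style == "upper":
        return name.upper()
    if style == "title":
        return name.title()
    return name.lower()


def _perturb_separators(name: str, rng: Random, rate: float) -> str:
    out = []
    for ch in name:
        if ch == " " and rng.random() < rate:
            out.append("-")
        elif ch == "-" and rng.random() < rate:
            out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def _perturb_typos(name: str, rng: Random, rate: float) -> str:
    letters = string.ascii_lowercase
    out: List[str] = []
    for ch in name:
        if ch.isalpha() and rng.random() < rate:
            kind = rng.choice(("substitute", "delete", "insert"))
            if kind == "substitute":
                repl = rng.choice(letters)
                out.append(repl.upper() if ch.isupper() else repl)
            elif kind == "insert":
                out.append(ch)
                out.append(rng.choice(letters))
            # delete: append nothing
        else:
            out.append(ch)
    mutated = "".join(out)
    # a typo must never blank the name or change its normalized key to
    # nothing; fall back to the original in that degenerate case
    return mutated if canonicalize_text(mutated) else name


def _perturb(
    name: str, rng: Random, params: PerturbationParams, allow_typo: bool = True
) -> str:
    if rng.random() < params.case_flip_rate:
        name = _perturb_case(name, rng)
    name = _perturb_separators(name, rng, params.hyphenation_rate)
    if allow_typo and params.typo_rate > 0:
        name = _perturb_typos(name, rng, params.typo_rate)
    return name


def _random_seq(length: int, rng: Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _marker_plan(lexicon: SynonymTable, organelle: str) -> List[Tuple[str, List[str]]]:
    """(short_name, long-form candidates) per canonical marker, in order."""
    plan = []
    for gene in lexicon.canonical_genes(organelle):
        variants = lexicon.variants_of(gene.short_name, organelle)
        long_forms = variants[1:] or [gene.short_name]
        plan.append((gene.short_name, long_forms))
    return plan


def _build_record(
    index: int,
    organelle: str,
    plan: List[Tuple[str, List[str]]],
    params: PerturbationParams,
    rng: Random,
    truth: Dict[str, str],
    known_keys: Dict[str, str],
) -> SeqRecord:
    accession = f"SYN{organelle.upper()}{index:05d}"
    features: List[SeqFeature] = []
    position = 0

    def next_location() -> FeatureLocation:
        nonlocal position
        loc = FeatureLocation(position, position + _FEATURE_SPAN)
        position += _FEATURE_SPAN
        return loc

    def guarded(perturbed: str, base: str, short: str) -> str:
        # a perturbation must never collide with a different marker's name
        # (e.g. a deletion turning "photosystem II ..." into the matching
        # "photosystem I ..." form); fall back to the unperturbed spelling
        key = canonicalize_text(perturbed)
        owner = known_keys.get(key)
        if owner is not None and owner != short:
            return base
        known_keys[key] = short
        known_keys.setdefault(canonicalize_text(base), short)
        return perturbed

    for short, long_forms in plan:
        base = rng.choice(long_forms)
        if short == "Control Region":
            # no /gene qualifier, like real D-loop annotations; typos are
            # withheld so the note always resolves through the lexicon
            note = _perturb(base, rng, params, allow_typo=False)
            features.append(
                SeqFeature(
                    next_location(),
                    type="D-loop",
                    qualifiers={"note": [note]},
                )
            )
            truth[note] = short
            continue
        product = guarded(_perturb(base, rng, params, allow_typo=True), base, short)
        kind = "rRNA" if short in _RRNA_MARKERS else "CDS"
        qualifiers = {"gene": [short], "product": [product]}
        if kind == "CDS":
            qualifiers["codon_start"] = ["1"]
        features.append(SeqFeature(next_location(), type=kind, qualifiers=qualifiers))
        truth[short] = short
        truth[product] = short
    # one decoy tRNA, which the scanner must ignore
    features.append(
        SeqFeature(
            next_location(),
            type="tRNA",
            qualifiers={"gene": ["trnF"], "product": ["tRNA-Phe"]},
        )
    )
    seq = Seq(_random_seq(position, rng))
    record = SeqRecord(
        seq,
        id=accession,
        name=accession,
        description=f"synthetic {organelle} organelle genome, synthetic fixture",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "accessions": [accession],
        },
    )
    source = SeqFeature(
        FeatureLocation(0, len(seq)),
        type="source",
        qualifiers={"organism": ["synthetic organism"]},
    )
    record.features = [source] + features
    return record


def generate_corpus(
    n_genomes: int,
    organelle: str,
    seed: int,
    params: Optional[PerturbationParams] = None,
    out_dir: Union[str, Path] = "fixtures",
    lexicon: Optional[SynonymTable] = None,
) -> Tuple[List[Path], FixtureTruth]:
    """Write *n_genomes* synthetic GenBank files plus a ground-truth map.

    Each genome covers every canonical marker of *organelle* once, with a
    long-form product name sampled from *lexicon* (the packaged seed table
    by default) and perturbed at the given rates.  Returns the list of
    ``.gb`` paths and the :class:`FixtureTruth`; the truth is also written
    as ``truth.json`` next to the genomes.  Identical arguments produce a
    byte-identical corpus.
    """
    if organelle not in ORGANELLES:
        raise ValueError(f"organelle must be one of {ORGANELLES}")
    if n_genomes < 0:
        raise ValueError("n_genomes must be non-negative")
    params = params or PerturbationParams()
    params.validate()
    lexicon = lexicon or load_seed_table()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = _marker_plan(lexicon, organelle)
    rng = Random(seed)
    truth_map: Dict[str, str] = {}
    # normalized key -> owning marker, pre-seeded with the whole lexicon so
    # perturbations cannot silently land on another marker's name
    known_keys: Dict[str, str] = dict(lexicon.as_mapping(organelle))
    paths: List[Path] = []
    for i in range(n_genomes):
        record = _build_record(
            i, organelle, plan, params, rng, truth_map, known_keys
        )
        path = out_dir / f"{record.id}.gb"
        with open(path, "w", encoding="utf-8") as fh:
            SeqIO.write(record, fh, "genbank")
        paths.append(path)
    truth = FixtureTruth(truth_map, organelle, seed, params)
    truth.save(out_dir / "truth.json")
    return paths, truth
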