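"""Seed-site and AU-rich-element scanning of 3'UTR sequences.

Canonical miRNA seed sites are matches on the mRNA (written 5'->3') to the
reverse complement of the miRNA seed region:

* 6mer     -- reverse complement of miRNA nucleotides 2-7;
* 7mer-m8  -- reverse complement of nucleotides 2-8;
* 7mer-A1  -- the 6mer followed by an A opposite miRNA position 1;
* 8mer     -- the 7mer-m8 followed by that A.

When patterns nest at one locus only the most specific type is reported
(8mer > 7mer-m8 > 7mer-A1 > 6mer).  AU-rich elements are maximal runs of
overlapping AUUUA pentamers (overlap step 4, so AUUUAUUUA counts two), with
a cluster class capped at 5.  These local scanners stand in for web-based
target and ARE database lookups, whose underlying UTR databases and
versions they do not replicate.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}

_ARE_RE = re.compile("AUUUA(?:UUUA)*")


@dataclass(frozen=True)
class SeedSite:
    """A seed match on a UTR; 1-based inclusive coordinates, 5'->3'."""

    utr_id: str
    site_type: str
    start: int
    end: int


@dataclass(frozen=True)
class AREMatch:
    """A maximal AUUUA pentamer run; class = min(5, pentamer count)."""

    utr_id: str
    start: int
    n_overlapping_pentamers: int
    cluster_class: int


def reverse_complement(rna: str) -> str:
    """Reverse complement of an RNA string (ACGU alphabet)."""
    try:
        return "".join(_RC[c] for c in reversed(rna))
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc.args[0]!r}") from None


def normalize_rna(sequence: str, label: str = "sequence") -> str:
    """Uppercase and convert DNA T to U, warning once per call."""
    seq = sequence.upper()
    if "T" in seq:
        warnings.warn(f"{label}: DNA alphabet detected, converting T to U", stacklevel=2)
        seq = seq.replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)}")
    return seq


def seed_patterns(mirna_sequence: str) -> dict[str, str]:
    """The four canonical site patterns for a mature miRNA (5'->3').

    Patterns are the sequences searched for on the mRNA: the 6mer and
    7mer-m8 are reverse complements of miRNA nucleotides 2-7 and 2-8, and
    the A1 variants append an A (the base most often found opposite miRNA
    position 1 in functional sites, regardless of pairing).
    """
    mirna = normalize_rna(mirna_sequence, "miRNA")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt long")
    six = reverse_complement(mirna[1:7])
    m8 = reverse_complement(mirna[1:8])
    return {"6mer": six, "7mer-A1": six + "A", "7mer-m8": m8, "8mer": m8 + "A"}


def find_seed_sites(mirna_sequence: str, utr_sequence: str, utr_id: str = "utr") -> list[SeedSite]:
    """All seed sites of a miRNA on one UTR, most specific type per locus.

    Each occurrence of the core 6mer defines a locus; the locus is upgraded
    by a matching m8 base immediately 5' of the core and/or an A immediately
    3' of it.  Overlapping loci are each reported.  Returned sites are
    sorted by start, then type specificity.
    """
    patterns = seed_patterns(mirna_sequence)
    utr = normalize_rna(utr_sequence, utr_id)
    if not utr:
        raise ValueError("empty UTR")
    core = patterns["6mer"]
    m8_base = patterns["7mer-m8"][0]
    sites: list[SeedSite] = []
    q = utr.find(core)
    while q != -1:
        has_m8 = q > 0 and utr[q - 1] == m8_base
        has_a1 = q + 6 < len(utr) and utr[q + 6] == "A"
        if has_m8 and has_a1:
            stype, start0, length = "8mer", q - 1, 8
        elif has_m8:
            stype, start0, length = "7mer-m8", q - 1, 7
        elif has_a1:
            stype, start0, length = "7mer-A1", q, 7
        else:
            stype, start0, length = "6mer", q, 6
        # Internal scan is 0-based half-open; reports are 1-based inclusive.
        sites.append(SeedSite(utr_id, stype, start0 + 1, start0 + length))
        q = utr.find(core, q + 1)
    sites.sort(key=lambda s: (s.start, SITE_PRIORITY.index(s.site_type)))
    return sites


def find_are_motifs(utr_sequence: str, utr_id: str = "utr") -> list[AREMatch]:
    """Maximal runs of overlapping AUUUA pentamers on one UTR.

    A run of length 5 + 4(k-1) holds k pentamers at step 4; the cluster
    class is min(5, k).  Matches are non-overlapping and reported in
    increasing position order (1-based).
    """
    utr = normalize_rna(utr_sequence, utr_id)
    matches = []
    for m in _ARE_RE.finditer(utr):
        k = (m.end() - m.start() - 1) // 4
        matches.append(AREMatch(utr_id, m.start() + 1, k, min(5, k)))
    return matches


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``, rejecting duplicate ids."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def annotate_candidates(
    candidates: pd.DataFrame,
    utrs: Mapping[str, str] | str | Path,
    mirna_sequence: str,
    gene_col: str = "gene_id",
) -> pd.DataFrame:
    """Attach seed-site and ARE flags to a candidate-gene table.

    ``utrs`` maps gene id to 3'UTR sequence (or is a FASTA path).  Genes
    without a UTR record get ``annotation_status = "missing_utr"`` and NA
    flags rather than a silent False.
    """
    if not isinstance(utrs, Mapping):
        utrs = read_fasta(utrs)
    if candidates[gene_col].duplicated().any():
        dups = candidates[gene_col][candidates[gene_col].duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in candidate table: {dups}")
    out = candidates.copy()
    seed_flags, are_flags, status, n_sites, n_ares, best_type = [], [], [], [], [], []
    for gene in out[gene_col]:
        utr = utrs.get(gene)
        if utr is None:
            seed_flags.append(pd.NA)
            are_flags.append(pd.NA)
            status.append("missing_utr")
            n_sites.append(0)
            n_ares.append(0)
            best_type.append("")
            continue
        sites = find_seed_sites(mirna_sequence, utr, utr_id=gene)
        ares = find_are_motifs(utr, utr_id=gene)
        seed_flags.append(bool(sites))
        are_flags.append(bool(ares))
        status.append("annotated")
        n_sites.append(len(sites))
        n_ares.append(len(ares))
        best = min((SITE_PRIORITY.index(s.site_type) for s in sites), default=None)
        best_type.append(SITE_PRIORITY[best] if best is not None else "")
    out["seed_site"] = pd.array(seed_flags, dtype="boolean")
    out["has_are"] = pd.array(are_flags, dtype="boolean")
    out["n_seed_sites"] = n_sites
    out["n_are_motifs"] = n_ares
    out["best_site_type"] = best_type
    out["annotation_status"] = status
    return out


def sites_to_frame(sites: Iterable[SeedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.utr_id, s.site_type, s.start, s.end) for s in sites],
        columns=["utr_id", "site_type", "start", "end"],
    )


def ares_to_frame(matches: Iterable[AREMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.utr_id, m.start, m.n_overlapping_pentamers, m.cluster_class) for m in matches],
        columns=["utr_id", "start", "n_overlapping_pentamers", "cluster_class"],
    )
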