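"""Catalytic-site detection and peroxidase typing.

Class-II peroxidase families differ by two substrate-oxidation sites: the
Mn²⁺-binding acidic triad (two glutamates and one aspartate; Glu37, Glu41,
Asp183 in the ancestors' numbering) and an exposed catalytic tryptophan
(Trp172) that oxidizes nonphenolic lignin by long-range electron transfer.
A sequence with the intact triad and no tryptophan is a manganese
peroxidase (MnP); triad plus tryptophan is a versatile peroxidase (VP);
tryptophan with a degraded triad is a lignin peroxidase (LiP); neither site
is a generic peroxidase (GP).  A triad with one residue replaced is
"atypical" (weak Mn²⁺ oxidation) unless the replacement is basic (Arg/Lys),
which blocks cation binding outright.

Residue matching is exact (Glu vs Asp distinguished): an Asp at position 37
does not support Mn²⁺ oxidation even though it is acidic.  Positions and
required residues are configuration, so the rules generalize to other
numbering schemes or families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alignment import GAP, SiteMap
from .sampling import AncestorSet


class TypingError(ValueError):
    pass


@dataclass
class SiteRules:
    """Named positions and required residues for the two oxidation sites."""

    triad: list[tuple[str, str]] = field(
        default_factory=lambda: [("37", "E"), ("41", "E"), ("183", "D")])
    trp: tuple[str, str] = ("172", "W")
    basic: frozenset[str] = frozenset({"R", "K"})

    @classmethod
    def from_dict(cls, d: dict) -> "SiteRules":
        return cls(
            triad=[(str(p["position"]), p["residue"]) for p in d["triad"]],
            trp=(str(d["trp"]["position"]), d["trp"]["residue"]),
            basic=frozenset(d.get("basic", ["R", "K"])),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SiteRules":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "triad": [{"position": p, "residue": r} for p, r in self.triad],
            "trp": {"position": self.trp[0], "residue": self.trp[1]},
            "basic": sorted(self.basic),
        }

    def all_labels(self) -> list[str]:
        return [p for p, _ in self.triad] + [self.trp[0]]


#: (mn_site, has_catalytic_trp) -> peroxidase type.  Total mapping.
TYPE_TABLE = {
    ("typical", True): "VP",
    ("typical", False): "MnP",
    ("atypical", True): "VP-atypical",
    ("atypical", False): "MnP-atypical",
    ("blocked", True): "LiP",
    ("blocked", False): "GP",
    ("none", True): "LiP",
    ("none", False): "GP",
}


@dataclass
class CatalyticProfile:
    residues: dict[str, str]
    exact_triad_matches: int
    third_position_basic: bool
    has_catalytic_trp: bool
    mn_site: str                      # typical | atypical | blocked | none
    type_label: str
    masked_positions: list[str] = field(default_factory=list)


def classify_catalytic_profile(seq: str, sites: SiteMap,
                               rules: SiteRules) -> CatalyticProfile:
    """Type one sequence (alignment coordinates) from its catalytic residues.

    A gap at a named position counts as a mismatch and is flagged in
    ``masked_positions``.
    """
    residues: dict[str, str] = {}
    masked: list[str] = []
    for label in rules.all_labels():
        col = sites.column(label)
        if col >= len(seq):
            raise TypingError(f"position '{label}' (column {col}) is outside "
                              f"the sequence (length {len(seq)})")
        residues[label] = seq[col]
        if seq[col] == GAP:
            masked.append(label)

    matches = sum(residues[p] == want for p, want in rules.triad)
    mismatch_basic = any(residues[p] != want and residues[p] in rules.basic
                         for p, want in rules.triad)
    if matches == 3:
        mn_site = "typical"
    elif matches == 2:
        mn_site = "blocked" if mismatch_basic else "atypical"
    else:
        mn_site = "none"
    has_trp = residues[rules.trp[0]] == rules.trp[1]
    return CatalyticProfile(residues, matches, mismatch_basic, has_trp,
                            mn_site, TYPE_TABLE[(mn_site, has_trp)], masked)


#: mn_site -> subset name used when partitioning a sampled ancestor set.
SUBSET_OF_MN_SITE = {
    "typical": "typical-triad",
    "atypical": "atypical",
    "blocked": "basic-blocked",
    "none": "other",
}


@dataclass
class SetPartition:
    node: str
    subset_fractions: dict[str, float]
    type_fractions: dict[str, float]
    subset_of_sample: list[str]
    profile_of_sample: list[CatalyticProfile]


def partition_ancestor_set(aset: AncestorSet, sites: SiteMap,
                           rules: SiteRules) -> SetPartition:
    """Assign every sampled ancestor to a triad subset and a peroxidase type.

    Mirrors the subset analysis applied to the sampled sequences of the
    oldest node: intact triad / atypical (third residue non-basic) /
    basic-blocked / other, with per-type fractions reported alongside.
    """
    if not aset.samples:
        raise TypingError("empty ancestor set")
    subsets, profiles = [], []
    type_counts: dict[str, int] = {}
    subset_counts: dict[str, int] = {}
    for seq in aset.samples:
        prof = classify_catalytic_profile(seq, sites, rules)
        sub = SUBSET_OF_MN_SITE[prof.mn_site]
        subsets.append(sub)
        profiles.append(prof)
        subset_counts[sub] = subset_counts.get(sub, 0) + 1
        type_counts[prof.type_label] = type_counts.get(prof.type_label, 0) + 1
    n = len(aset.samples)
    return SetPartition(
        aset.node,
        {k: v / n for k, v in sorted(subset_counts.items())},
        {k: v / n for k, v in sorted(type_counts.items())},
        subsets, profiles)
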