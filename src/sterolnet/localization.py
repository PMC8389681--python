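"""Subcellular-localization concordance filter (selection round 2).

A consensus edge survives only if the enzyme and the partner share at
least one annotated compartment ("overlap" policy).  A stricter
"membrane_system" policy additionally requires that shared membrane
compartments match when both proteins are membrane proteins.  Terms are
canonicalized through a synonym map so that abbreviated annotations
("ERM") and full names compare equal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .consensus import ConfigurationError, ConsensusEdge

logger = logging.getLogger(__name__)

__all__ = [
    "LocalizationProfile",
    "CompartmentVocabulary",
    "default_vocabulary",
    "load_localization_table",
    "enzyme_localization_table",
    "profiles_concordant",
    "apply_localization_filter",
]

_MEMBRANE_MARKER = "membrane"


@dataclass(frozen=True)
class LocalizationProfile:
    """Compartment annotation of one protein."""

    protein: str
    compartments: frozenset[str]

    @property
    def is_membrane(self) -> bool:
        return any(_MEMBRANE_MARKER in c for c in self.compartments)


class CompartmentVocabulary:
    """Controlled compartment terms plus a synonym map.

    Loading a localization table fails loudly on a term outside the
    vocabulary, naming the term and line, so silent typos cannot leak
    into the filter.
    """

    def __init__(self, terms: list[str], synonyms: dict[str, str] | None = None):
        self.terms = frozenset(t.strip().lower() for t in terms)
        self.synonyms = {k.strip().lower(): v.strip().lower() for k, v in (synonyms or {}).items()}
        for syn, target in self.synonyms.items():
            if target not in self.terms:
                raise ConfigurationError(f"synonym {syn!r} points to unknown term {target!r}")

    def canonicalize(self, term: str) -> str:
        t = term.strip().lower()
        t = self.synonyms.get(t, t)
        if t not in self.terms:
            raise ConfigurationError(f"compartment term {term!r} not in vocabulary")
        return t

    @classmethod
    def from_json(cls, path: str | Path) -> "CompartmentVocabulary":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["terms"], raw.get("synonyms"))


def default_vocabulary() -> CompartmentVocabulary:
    """Vocabulary shipped with the package (NextProt-style compartments)."""
    ref = resources.files("sterolnet.data") / "compartment_vocabulary.json"
    with resources.as_file(ref) as path:
        return CompartmentVocabulary.from_json(path)


def load_localization_table(
    path: str | Path, vocabulary: CompartmentVocabulary
) -> dict[str, LocalizationProfile]:
    """Read a protein -> semicolon-joined-compartments TSV.

    All terms are canonicalized through the synonym map; an unknown term
    raises, naming the term and the line number.
    """
    profiles: dict[str, LocalizationProfile] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ConfigurationError(f"line {lineno}: expected 2 tab-separated columns")
            protein = cols[0].strip()
            raw_terms = [t for t in cols[1].split(";") if t.strip()]
            if not raw_terms:
                raise ConfigurationError(f"line {lineno}: no compartments for {protein!r}")
            try:
                terms = frozenset(vocabulary.canonicalize(t) for t in raw_terms)
            except ConfigurationError as exc:
                raise ConfigurationError(f"line {lineno}: {exc}") from exc
            profiles[protein] = LocalizationProfile(protein, terms)
    if not profiles:
        logger.warning("%s: empty localization table", path)
    return profiles


def enzyme_localization_table() -> dict[str, LocalizationProfile]:
    """Compartment profiles of the 17 cholesterol-pathway enzymes.

    Twelve enzymes are membrane proteins (endoplasmic reticulum membrane
    and related membrane systems); MVK, PMVK, MVD, FDPS and LSS are the
    soluble minority (cytosol, peroxisomes, lipid droplets).
    """
    ref = resources.files("sterolnet.data") / "enzyme_localization.tsv"
    with resources.as_file(ref) as path:
        return load_localization_table(path, default_vocabulary())


def profiles_concordant(
    enzyme_profile: LocalizationProfile,
    partner_profile: LocalizationProfile,
    policy: str = "overlap",
) -> bool:
    """Decide localization concordance for one edge.

    ``overlap``: true iff the compartment sets intersect.
    ``membrane_system``: the intersection must contain a membrane term
    whenever both proteins are membrane proteins.
    """
    shared = enzyme_profile.compartments & partner_profile.compartments
    if policy == "overlap":
        return bool(shared)
    if policy == "membrane_system":
        if enzyme_profile.is_membrane and partner_profile.is_membrane:
            return any(_MEMBRANE_MARKER in c for c in shared)
        return bool(shared)
    raise ConfigurationError(f"unknown concordance policy {policy!r}")


def apply_localization_filter(
    edges: list[ConsensusEdge],
    profiles: dict[str, LocalizationProfile],
    policy: str = "overlap",
    missing: str = "keep_with_flag",
) -> tuple[list[ConsensusEdge], dict[tuple[str, str], str]]:
    """Retain edges with concordant enzyme/partner localization.

    Returns ``(kept_edges, status)`` where status maps each input pair to
    one of {"pass", "fail", "missing"}.  ``missing`` controls edges whose
    partner (or enzyme) has no profile: "drop", "keep" or the default
    "keep_with_flag" — annotation-coverage gaps should be visible, not
    destructive.
    """
    if missing not in {"drop", "keep", "keep_with_flag"}:
        raise ConfigurationError(f"unknown missing-profile policy {missing!r}")
    kept: list[ConsensusEdge] = []
    status: dict[tuple[str, str], str] = {}
    for edge in edges:
        ep = profiles.get(edge.enzyme)
        pp = profiles.get(edge.partner)
        if ep is None or pp is None:
            status[edge.pair] = "missing"
            if missing in {"keep", "keep_with_flag"}:
                kept.append(edge)
            continue
        if profiles_concordant(ep, pp, policy):
            status[edge.pair] = "pass"
            kept.append(edge)
        else:
            status[edge.pair] = "fail"
            logger.debug(
                "dropped %s-%s: %s vs %s",
                edge.enzyme,
                edge.partner,
                sorted(ep.compartments),
                sorted(pp.compartments),
            )
    return kept, status
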