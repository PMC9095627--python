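"""Registry of CRISPR endoRNases, their hairpin recognition sites, and
pairwise cross-reactivity.

The platform uses nine Cas6/Cas13-family endoribonucleases as RNA-level
regulators.  Each enzyme cleaves a short, usually hairpin-structured
recognition sequence (a "direct repeat"); placing that sequence in a
transcript's 5' UTR makes the enzyme a repressor, placing it inside a
3' ON motif makes it an activator.  Orthogonality between enzymes and
non-cognate hairpins is what lets several regulators operate in one
circuit, so the registry carries an explicit (enzyme, site) activity
matrix with cognate pairs normalized to 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "Family",
    "EndoRNase",
    "RecognitionSite",
    "CrossReactivityMatrix",
    "Registry",
    "default_registry",
    "cleavage_activity",
    "orthogonal_pairs",
]


class Family(str, enum.Enum):
    CAS6 = "Cas6"
    CAS13 = "Cas13"


@dataclass(frozen=True)
class EndoRNase:
    """One endoRNase part.

    Parameters
    ----------
    name : str
        Unique identifier (e.g. ``"Csy4"``).
    family : Family
        Cas6 (DNA-targeting systems' crRNA processors) or Cas13.
    vmax_rel : float
        Cognate cleavage capacity relative to the strongest enzyme in the
        registry; in (0, 1].
    K : float
        Enzyme level (protein a.u.) at which cleavage reaches half its
        maximal rate.
    pest_available : bool
        Whether a destabilized (PEST-tagged) variant exists for use in
        regulated intermediate layers.
    """

    name: str
    family: Family
    vmax_rel: float
    K: float
    pest_available: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.vmax_rel <= 1.0:
            raise ValueError(f"vmax_rel must be in (0, 1], got {self.vmax_rel}")
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")


@dataclass(frozen=True)
class RecognitionSite:
    """A cleavable hairpin/direct-repeat sequence element."""

    site_id: str
    cognate_enzyme: str
    description: str = ""


class CrossReactivityMatrix:
    """Complete (enzyme, site) -> activity map, activity in [0, 1].

    Cognate pairs are normalized to activity 1.  An activity of 0 means the
    enzyme does not cleave that hairpin at all; intermediate values scale
    the cognate cleavage capacity.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        for (enz, site), a in entries.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"activity({enz}, {site}) = {a} outside [0, 1]")
        self._entries = dict(entries)

    @property
    def entries(self) -> dict[tuple[str, str], float]:
        return dict(self._entries)

    def activity(self, enzyme: str, site_id: str) -> float:
        key = (enzyme, site_id)
        if key not in self._entries:
            raise KeyError(f"no cross-reactivity entry for enzyme {enzyme!r}, site {site_id!r}")
        return self._entries[key]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CrossReactivityMatrix) and self._entries == other._entries


@dataclass
class Registry:
    """Enzymes + sites + cross-reactivity, the shared part catalogue."""

    enzymes: list[EndoRNase]
    sites: list[RecognitionSite]
    matrix: CrossReactivityMatrix
    _by_name: dict = field(init=False, repr=False)
    _site_by_id: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.enzymes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate enzyme names in registry")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids in registry")
        self._by_name = {e.name: e for e in self.enzymes}
        self._site_by_id = {s.site_id: s for s in self.sites}
        for s in self.sites:
            if s.cognate_enzyme not in self._by_name:
                raise ValueError(f"site {s.site_id} names unknown cognate enzyme {s.cognate_enzyme}")
        # completeness + cognate normalization
        for e in self.enzymes:
            for s in self.sites:
                a = self.matrix.activity(e.name, s.site_id)
                if s.cognate_enzyme == e.name and a != 1.0:
                    raise ValueError(f"cognate pair ({e.name}, {s.site_id}) must have activity 1")

    def enzyme(self, name: str) -> EndoRNase:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown enzyme {name!r}") from None

    def site(self, site_id: str) -> RecognitionSite:
        try:
            return self._site_by_id[site_id]
        except KeyError:
            raise KeyError(f"unknown site {site_id!r}") from None

    def cognate_site(self, enzyme_name: str) -> RecognitionSite:
        """The wild-type site for an enzyme (first site listing it as cognate)."""
        for s in self.sites:
            if s.cognate_enzyme == enzyme_name and not s.site_id.endswith("star-site"):
                return s
        raise KeyError(f"no cognate site for enzyme {enzyme_name!r}")


def cleavage_activity(enzyme: EndoRNase | str, site: RecognitionSite | str,
                      matrix: CrossReactivityMatrix) -> float:
    """Fraction of cognate cleavage capacity for an (enzyme, site) pair."""
    name = enzyme.name if isinstance(enzyme, EndoRNase) else enzyme
    sid = site.site_id if isinstance(site, RecognitionSite) else site
    return matrix.activity(name, sid)


def orthogonal_pairs(matrix: CrossReactivityMatrix, threshold: float,
                     registry: Registry | None = None) -> list[tuple[str, str]]:
    """Flag every non-cognate (enzyme, site) pair with activity >= threshold.

    These are the pairs that should not share a circuit unless the
    cross-reactivity is wanted.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    cognate: dict[str, str] = {}
    if registry is not None:
        cognate = {s.site_id: s.cognate_enzyme for s in registry.sites}
    flagged = []
    for (enz, sid), a in sorted(matrix.entries.items()):
        is_cognate = cognate.get(sid) == enz if cognate else a == 1.0
        if not is_cognate and a >= threshold and a > 0:
            flagged.append((enz, sid))
    return flagged


def _registry_from_block(block: dict) -> Registry:
    enzymes = [
        EndoRNase(name=n, family=Family(v["family"]), vmax_rel=float(v["vmax_rel"]),
                  K=float(v["K"]), pest_available=bool(v.get("pest_available", False)))
        for n, v in block["enzymes"].items()
    ]
    sites = [
        RecognitionSite(site_id=sid, cognate_enzyme=v["cognate"],
                        description=v.get("description", ""))
        for sid, v in block["sites"].items()
    ]
    entries: dict[tuple[str, str], float] = {}
    for e in enzymes:
        for s in sites:
            entries[(e.name, s.site_id)] = 1.0 if s.cognate_enzyme == e.name else 0.0
    for row in block.get("off_target", []):
        entries[(row["enzyme"], row["site"])] = float(row["activity"])
    return Registry(enzymes=enzymes, sites=sites, matrix=CrossReactivityMatrix(entries))


def _registry_to_block(reg: Registry) -> dict:
    enzymes = {
        e.name: {"family": e.family.value, "vmax_rel": e.vmax_rel, "K": e.K,
                 "pest_available": e.pest_available}
        for e in reg.enzymes
    }
    sites = {s.site_id: {"cognate": s.cognate_enzyme, "description": s.description}
             for s in reg.sites}
    cognate = {s.site_id: s.cognate_enzyme for s in reg.sites}
    off = [
        {"enzyme": enz, "site": sid, "activity": a}
        for (enz, sid), a in sorted(reg.matrix.entries.items())
        if a > 0 and cognate[sid] != enz
    ]
    return {"enzymes": enzymes, "sites": sites, "off_target": off}


def default_registry() -> Registry:
    """The nine-enzyme catalogue with the documented cross-reactive pairs.

    Four Cas6-family enzymes (Csy4, Cse3, CasE, Cas6) and five Cas13-family
    enzymes (LwaCas13a, PspCas13b, PguCas13b, RanCas13b, RfxCas13d); ten
    sites, the tenth being the Cse3* U5A hairpin mutant which only Cse3
    cleaves.  Nonzero off-target entries: CasE on the wild-type Cse3
    hairpin, and the mutual RanCas13b/PguCas13b pair.
    """
    from .config import load_default_config

    return _registry_from_block(load_default_config()["registry"])


def write_registry(reg: Registry, path) -> None:
    """Serialize a registry as a structured YAML config block."""
    with open(path, "w") as fh:
        yaml.safe_dump({"registry": _registry_to_block(reg)}, fh, sort_keys=False)


def read_registry(path) -> Registry:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _registry_from_block(doc["registry"])
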