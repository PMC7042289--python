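"""Synthetic occurrence datasets with planted ground truth.

The generator emulates the statistical shape of a real herbarium occurrence
table without any external download:

* multi-collector ``recordedBy`` strings assembled with heterogeneous
  delimiters, optional spelling variants and "et al." truncation;
* a log-decaying team-size distribution (most records are single-collector,
  the default sizes 1..6 have mean 1.73);
* a configurable share of *individualist* collectors who only ever record
  alone;
* heavy-tailed per-collector activity, so a few hub collectors dominate the
  record counts;
* planted *interest communities*: groups of collectors who preferentially
  record species from their own small set of plant families and
  preferentially team up with each other, so the species-collector network
  carries taxonomic structure and the coworking network carries community
  structure that downstream analytics should recover.

What it does **not** emulate: temporal or geographic realism (dates and
places are filler), taxonomy beyond a flat species→family map, and the
deeper messiness of historical transcription (OCR noise, swapped name
orders, institution strings in ``recordedBy``).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from colnet.errors import ConfigurationError

# Deterministic pseudo-Latin building blocks for taxon names.
_FAMILY_STEMS = (
    "Aster", "Fab", "Poa", "Rubi", "Myrt", "Cyper", "Orchid", "Malv",
    "Euphorbi", "Apocyn", "Lami", "Solan", "Bignoni", "Melastomat", "Annon",
    "Laur", "Sapind", "Verben", "Arec", "Brome", "Acanth", "Amaranth",
    "Boragin", "Cact",
)
_EPITHETS = (
    "alba", "nitida", "gracilis", "robusta", "minor", "major", "elegans",
    "parviflora", "grandiflora", "angustifolia", "latifolia", "glabra",
    "hirsuta", "pilosa", "velutina", "aurea", "argentea", "coriacea",
    "cordata", "ovata", "lanceolata", "obtusa", "acuminata", "racemosa",
    "paniculata", "spicata", "umbellata", "sessilis", "petiolata", "rupestris",
    "campestris", "sylvestris", "palustris", "riparia", "montana", "australis",
    "brasiliensis", "cerradensis", "occidentalis", "orientalis",
)
_SURNAMES = (
    "Silva", "Santos", "Oliveira", "Souza", "Pereira", "Lima", "Carvalho",
    "Ribeiro", "Almeida", "Costa", "Gomes", "Martins", "Araújo", "Barbosa",
    "Rocha", "Dias", "Nascimento", "Andrade", "Moreira", "Nunes", "Marques",
    "Machado", "Mendes", "Freitas", "Cardoso", "Ramos", "Gonçalves",
    "Teixeira", "Fernandes", "Vieira", "Monteiro", "Moura", "Cavalcanti",
    "Proença", "Azevedo", "Camargo", "Tavares", "Farias", "Peixoto",
    "Sampaio", "Correia", "Batista", "Duarte", "Queiroz", "Fonseca",
    "Magalhães", "Brandão", "Siqueira",
)


@dataclass
class NameNoise:
    """Probabilities of the name-quality defects seen in real tables."""

    variant_prob: float = 0.0  # chance a member is written with a spelling variant
    et_al_prob: float = 0.0  # chance a multi-collector record keeps only its first name + "et al."
    delimiters: tuple[str, ...] = ("; ", " | ", " & ")  # drawn per record

    def __post_init__(self):
        for p in (self.variant_prob, self.et_al_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("name-noise probabilities must be in [0, 1]")
        if not self.delimiters:
            raise ConfigurationError("at least one delimiter is required")


# Mean 1.73, log-decaying — the typical shape of records-per-team-size in
# herbarium data, where most records are single-collector.
DEFAULT_TEAM_SIZE_PROBS: dict[int, float] = {1: 0.55, 2: 0.28, 3: 0.10, 4: 0.04, 5: 0.02, 6: 0.01}


@dataclass
class GeneratorConfig:
    n_collectors: int = 200
    n_species: int = 400
    n_families: int = 20
    n_records: int = 5000
    interest_communities: int = 4
    species_concentration: float = 0.9  # P(species drawn from the chooser's preferred family)
    team_coherence: float = 0.95  # P(teammates drawn from the lead's own community)
    team_size_probs: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_TEAM_SIZE_PROBS))
    individualist_fraction: float = 0.395
    activity_exponent: float = 0.8  # Zipf-like tail of per-collector activity
    name_noise: NameNoise = field(default_factory=NameNoise)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_collectors, self.n_species, self.n_families, self.n_records) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.interest_communities < 1 or self.interest_communities > self.n_collectors:
            raise ConfigurationError("interest_communities must be in [1, n_collectors]")
        if self.n_families < self.interest_communities:
            raise ConfigurationError("need at least one family per interest community")
        total = sum(self.team_size_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"team_size_probs must sum to 1 (got {total})")
        if any(s < 1 for s in self.team_size_probs):
            raise ConfigurationError("team sizes must be >= 1")
        if not 0.0 <= self.individualist_fraction <= 1.0:
            raise ConfigurationError("individualist_fraction must be in [0, 1]")
        collaborative_mass = sum(p for s, p in self.team_size_probs.items() if s >= 2)
        n_sociable = self.n_collectors - int(self.individualist_fraction * self.n_collectors)
        if collaborative_mass > 0 and n_sociable < 2:
            raise ConfigurationError(
                "infeasible: collaborative teams requested but fewer than two sociable collectors"
            )

    def mean_team_size(self) -> float:
        return sum(s * p for s, p in self.team_size_probs.items())


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline should recover."""

    record_members: dict[str, tuple[str, ...]]  # record_id -> canonical collector ids
    record_species: dict[str, str]
    community: dict[str, int]  # collector id -> planted interest community
    preferred_family: dict[str, str]  # collector id -> planted preferred family
    individualists: frozenset[str]  # collectors never in a team of size >= 2
    name_map: dict[str, str]  # variant token -> canonical token
    species_to_family: dict[str, str]
    team_sizes: list[int]

    def collectors(self) -> set[str]:
        return set(self.community)

    def write_sidecar(self, path) -> None:
        """Persist per-collector truth as a delimited table."""
        rows = [
            {
                "collector_id": cid,
                "community": self.community[cid],
                "preferred_family": self.preferred_family[cid],
                "individualist": cid in self.individualists,
            }
            for cid in sorted(self.community)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _species_names(n_species: int, n_families: int) -> tuple[list[str], list[str], dict[str, str]]:
    families = [
        f"{_FAMILY_STEMS[i % len(_FAMILY_STEMS)]}{'' if i < len(_FAMILY_STEMS) else i}aceae"
        for i in range(n_families)
    ]
    species: list[str] = []
    species_to_family: dict[str, str] = {}
    for j in range(n_species):
        fam_idx = j % n_families
        within = j // n_families
        genus = f"{_FAMILY_STEMS[fam_idx % len(_FAMILY_STEMS)]}ia"
        ep = _EPITHETS[within % len(_EPITHETS)]
        suffix = "" if within < len(_EPITHETS) else f" var{within // len(_EPITHETS)}"
        name = f"{genus} {ep}{suffix}"
        if fam_idx >= len(_FAMILY_STEMS):
            name = f"{genus}{fam_idx} {ep}{suffix}"
        species.append(name)
        species_to_family[name] = families[fam_idx]
    return species, families, species_to_family


def _collector_roster(n: int, rng: np.random.Generator):
    """Display names, canonical ids, and optional variant spellings.

    Ids must be unique: the canonical token is ``surname,initials`` so we
    grow the initials until no collision remains.
    """
    from colnet.name_resolution import normalize

    display: list[str] = []
    ids: list[str] = []
    variants: dict[str, str] = {}  # variant display -> collector index (by id)
    taken: set[str] = set()
    letters = string.ascii_uppercase
    for i in range(n):
        surname = _SURNAMES[i % len(_SURNAMES)]
        n_init = 2 + int(rng.integers(0, 2))  # 2 or 3 initials
        while True:
            initials = "".join(rng.choice(list(letters), size=n_init))
            disp = f"{surname}, {'.'.join(initials)}."
            token = normalize(disp)
            if token not in taken:
                break
            n_init = min(n_init + 1, 4)
        taken.add(token)
        display.append(disp)
        ids.append(token)
    # A spelling variant per collector: drop the final initial. Usable only
    # when the shortened token does not collide with any canonical id.
    variant_display: list[Optional[str]] = []
    variant_map: dict[str, str] = {}
    for i, disp in enumerate(display):
        surname, _, given = disp.partition(", ")
        inits = given.rstrip(".").split(".")
        if len(inits) >= 2:
            short = f"{surname}, {'.'.join(inits[:-1])}."
            token = normalize(short)
            if token not in taken and variant_map.get(token, ids[i]) == ids[i]:
                variant_display.append(short)
                variant_map[token] = ids[i]
                continue
        variant_display.append(None)
    return display, ids, variant_display, variant_map


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an occurrence table plus its ground truth.

    Fully reproducible: the same config (including seed) yields a
    byte-identical table.  Every sociable collector is guaranteed at least
    one collaborative record (a size-2 record replaces a single-collector one
    if the random draw left them without), so the realized individualist set
    equals the planted one.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    species, families, species_to_family = _species_names(cfg.n_species, cfg.n_families)
    species_by_family: dict[str, list[str]] = {f: [] for f in families}
    for s in species:
        species_by_family[species_to_family[s]].append(s)

    display, ids, variant_display, variant_map = _collector_roster(cfg.n_collectors, rng)
    idx_of = {cid: i for i, cid in enumerate(ids)}

    # communities and preferred families
    g = cfg.interest_communities
    perm = rng.permutation(cfg.n_collectors)
    community = {ids[i]: int(k % g) for k, i in enumerate(perm)}
    fams_of_comm = {c: [families[f] for f in range(cfg.n_families) if f % g == c] for c in range(g)}
    preferred = {
        cid: fams_of_comm[community[cid]][int(rng.integers(0, len(fams_of_comm[community[cid]])))]
        for cid in ids
    }

    n_indiv = int(cfg.individualist_fraction * cfg.n_collectors)
    indiv_idx = set(rng.choice(cfg.n_collectors, size=n_indiv, replace=False).tolist())
    sociable_idx = [i for i in range(cfg.n_collectors) if i not in indiv_idx]

    # heavy-tailed activity: weight ~ rank^{-alpha} over a random rank order
    rank = np.empty(cfg.n_collectors, dtype=int)
    rank[rng.permutation(cfg.n_collectors)] = np.arange(cfg.n_collectors)
    activity = (rank + 1.0) ** (-cfg.activity_exponent)
    p_all = activity / activity.sum()
    soc = np.array(sociable_idx, dtype=int)
    p_soc = activity[soc] / activity[soc].sum() if len(soc) else None
    soc_by_comm = {
        c: np.array([i for i in sociable_idx if community[ids[i]] == c], dtype=int) for c in range(g)
    }
    p_soc_comm = {
        c: activity[v] / activity[v].sum() for c, v in soc_by_comm.items() if len(v)
    }

    sizes = np.array(sorted(cfg.team_size_probs), dtype=int)
    size_p = np.array([cfg.team_size_probs[int(s)] for s in sizes])

    def sample_team(size: int) -> list[int]:
        if size == 1:
            return [int(rng.choice(cfg.n_collectors, p=p_all))]
        lead = int(rng.choice(soc, p=p_soc))
        comm = community[ids[lead]]
        if rng.random() >= cfg.team_coherence:
            comm = int(rng.integers(0, g))
        pool = soc_by_comm.get(comm)
        if pool is None or len(pool) < 2:
            pool, pw = soc, p_soc
        else:
            pw = p_soc_comm[comm]
        members = [lead]
        guard = 0
        while len(members) < size and guard < 200:
            cand = int(rng.choice(pool, p=pw))
            if cand not in members:
                members.append(cand)
            guard += 1
        return members

    def sample_species(chooser: int) -> str:
        if rng.random() < cfg.species_concentration:
            fam_pool = species_by_family[preferred[ids[chooser]]]
            if fam_pool:
                return fam_pool[int(rng.integers(0, len(fam_pool)))]
        return species[int(rng.integers(0, cfg.n_species))]

    teams: list[list[int]] = []
    for _ in range(cfg.n_records):
        size = int(rng.choice(sizes, p=size_p))
        teams.append(sample_team(size))

    # guarantee every sociable collector one collaborative appearance
    in_collab = {m for t in teams if len(t) >= 2 for m in t}
    missing = [i for i in sociable_idx if i not in in_collab]
    solo_slots = [k for k, t in enumerate(teams) if len(t) == 1]
    for i in missing:
        comm_pool = soc_by_comm.get(community[ids[i]])
        partner_pool = [int(x) for x in (comm_pool if comm_pool is not None else soc) if int(x) != i]
        if not partner_pool:
            partner_pool = [int(x) for x in soc if int(x) != i]
        if not partner_pool:
            break
        partner = partner_pool[int(rng.integers(0, len(partner_pool)))]
        team = [i, partner]
        if solo_slots:
            teams[solo_slots.pop()] = team
        else:
            teams.append(team)

    # assemble table + truth
    rows = []
    record_members: dict[str, tuple[str, ...]] = {}
    record_species: dict[str, str] = {}
    team_sizes: list[int] = []
    noise = cfg.name_noise
    for k, team in enumerate(teams):
        rid = f"r{k}"
        chooser = team[int(rng.integers(0, len(team)))]
        sp = sample_species(chooser)
        names = []
        for m in team:
            if variant_display[m] is not None and rng.random() < noise.variant_prob:
                names.append(variant_display[m])
            else:
                names.append(display[m])
        if len(team) >= 2 and rng.random() < noise.et_al_prob:
            recorded_by = f"{names[0]} et al."
        else:
            delim = noise.delimiters[int(rng.integers(0, len(noise.delimiters)))]
            recorded_by = delim.join(names)
        rows.append(
            {
                "record_id": rid,
                "recordedBy": recorded_by,
                "scientificName": sp,
                "taxonRank": "species",
                "family": species_to_family[sp],
                "eventDate": f"{1970 + k % 48}-0{1 + k % 9}-15",
                "countryCode": "BR",
                "stateProvince": "Distrito Federal",
            }
        )
        record_members[rid] = tuple(ids[m] for m in team)
        record_species[rid] = sp
        team_sizes.append(len(team))

    present = {cid for members in record_members.values() for cid in members}
    collab = {cid for members in record_members.values() if len(members) >= 2 for cid in members}
    truth = GroundTruth(
        record_members=record_members,
        record_species=record_species,
        community={cid: community[cid] for cid in present},
        preferred_family={cid: preferred[cid] for cid in present},
        individualists=frozenset(present - collab),
        name_map=dict(variant_map),
        species_to_family=species_to_family,
        team_sizes=team_sizes,
    )
    return pd.DataFrame(rows), truth


def ground_truth_eval(assignment: Mapping, truth: Mapping) -> float:
    """Label-permutation-invariant agreement between a detected partition and
    planted labels: each detected community is mapped to its majority planted
    label, and the score is the fraction of nodes whose planted label matches
    that of their community (best-match accuracy, in [0, 1])."""
    if set(assignment) != set(truth):
        raise ValueError("assignment and truth must cover the same node set")
    if not assignment:
        raise ValueError("empty partition")
    by_comm: dict = {}
    for node, cid in assignment.items():
        by_comm.setdefault(cid, []).append(node)
    correct = 0
    for members in by_comm.values():
        labels = [truth[n] for n in members]
        best = max(set(labels), key=labels.count)
        correct += labels.count(best)
    return correct / len(assignment)
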