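"""Synthetic communities with planted cross-feeding / competition structure.

The generator emulates the shape of literature-derived training data — a pool
of ~3,141 reactions, organisms carrying ~793 reactions on average, and a
roughly 3.86:1 cross-feeding:competition class ratio — while planting a
recoverable interaction signal:

* the head of the reaction pool is partitioned into disjoint *modules*
  (blocks of reactions standing in for pathways).  Each metabolic *guild* g
  owns a producer module ``P_g`` (synthesis and secretion of guild g's
  by-product) and a consumer module ``C_g`` (catabolism of that by-product,
  carried by the next guild in the feeding cycle); each substrate family f
  owns a resource module ``R_f`` (uptake and catabolism of that substrate);
  and each *habitat* m owns a larger habitat module ``H_m`` standing in for
  the core functions a niche demands (oxygen tolerance, bile resistance,
  temperature range ...);
* every organism gets a guild, a preferred substrate family and a habitat,
  drawn uniformly and independently.  A member of guild g preferring
  substrate f in habitat m carries ``P_g``, ``C_{g-1}`` (it grows on the
  by-product of the previous guild), ``R_f`` and ``H_m``, whole blocks
  switched on, plus background reactions drawn uniformly from the non-module
  remainder of the pool;
* interactions are planted between co-occurring organisms (same habitat;
  the constraint is relaxed to the whole community only when a habitat
  offers no eligible partner).  A cross-feeding pair is, with probability
  ``alpha``, drawn as (A in guild g, B in guild g+1) — so A carries a
  producer module whose paired consumer module B carries; with probability
  1-alpha it is a uniformly random pair (a cross-feeding report the reaction
  profiles cannot explain);
* a competition pair is, with probability ``beta``, drawn between two
  organisms that prefer the same substrate — both carry the same resource
  module — but sit in guilds at feeding-cycle distance >= 2 (niche overlap
  without a feeding relation); with probability 1-beta it is uniformly
  random;
* recorded labels are flipped with probability ``eta`` (label noise); the
  planted ground truth is returned separately.

Because pairs form within habitats, the strongest similarity structure among
pair vectors is the habitat signature, which is independent of the label.
Fold construction that clusters similar pairs therefore groups communities
and holds them out whole — exactly what leakage-aware evaluation intends —
while the label-bearing guild/resource patterns remain represented in every
fold.  The signal itself lives only in reaction-presence patterns: organism
IDs and vector order carry nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._exceptions import ValidationError
from .encoding import (
    COMPETITION,
    CROSS_FEEDING,
    InteractionRecord,
    PairDataset,
    ReactionPool,
    ReactionSet,
    augment_dataset,
    build_reaction_pool,
    encode_profile,
)

__all__ = [
    "GeneratorConfig",
    "Community",
    "generate_community",
    "plant_interactions",
    "generate_dataset",
    "make_fixture",
    "PRESETS",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic community generator.

    Defaults mirror the scale of the real training collection: a pool of
    3,141 reactions, 260 organisms averaging 793 reactions each, and
    1,053 cross-feeding / 273 competition pairs, organised as 4 guilds,
    2 substrate families and 10 habitats.
    """

    pool_size: int = 3141
    n_organisms: int = 260
    mean_reactions: int = 793
    n_guilds: int = 4
    n_resources: int = 2
    module_size: int = 80      # producer/consumer/resource pathway blocks
    n_habitats: int = 10
    habitat_size: int = 180    # niche core-function blocks
    alpha: float = 1.0         # P(cross-feeding pair links complementary guilds)
    beta: float = 1.0          # P(competition pair shares a resource module)
    eta: float = 0.0           # label-noise rate
    n_cf: int = 1053
    n_co: int = 273
    seed: int = 0

    def __post_init__(self):
        if self.n_guilds < 4:
            raise ValidationError(
                "need at least 4 guilds: competition links guilds at feeding-cycle "
                "distance >= 2"
            )
        if self.n_resources < 1 or self.n_habitats < 1:
            raise ValidationError("need at least one substrate family and one habitat")
        if self.module_region > self.pool_size:
            raise ValidationError("modules do not fit in the pool")
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1 and 0 <= self.eta <= 1):
            raise ValidationError("alpha, beta, eta must lie in [0, 1]")
        if self.mean_reactions > self.pool_size:
            raise ValidationError("mean reactions per organism exceeds the pool size")
        per_organism_blocks = 3 * self.module_size + self.habitat_size
        if self.mean_reactions <= per_organism_blocks:
            raise ValidationError(
                "mean_reactions too small for three pathway modules plus a habitat module"
            )
        background = self.mean_reactions - per_organism_blocks
        if background > self.pool_size - self.module_region:
            raise ValidationError("background density infeasible: mean exceeds non-module slots")
        if self.n_cf < 1 or self.n_co < 1:
            raise ValidationError("pair counts must be positive")
        max_pairs = self.n_organisms * (self.n_organisms - 1) // 2
        if self.n_cf + self.n_co > max_pairs:
            raise ValidationError(
                f"{self.n_cf + self.n_co} pairs requested but only C({self.n_organisms},2)"
                f"={max_pairs} exist"
            )

    @property
    def n_modules(self) -> int:
        """Number of metabolic pathway blocks (producer/consumer pairs + resources)."""
        return 2 * self.n_guilds + self.n_resources

    @property
    def module_region(self) -> int:
        return self.n_modules * self.module_size + self.n_habitats * self.habitat_size

    def module_block(self, module: int) -> range:
        """Pool index range of one pathway module block."""
        return range(module * self.module_size, (module + 1) * self.module_size)

    def habitat_block(self, habitat: int) -> range:
        start = self.n_modules * self.module_size + habitat * self.habitat_size
        return range(start, start + self.habitat_size)

    def producer_module(self, guild: int) -> int:
        return 2 * guild

    def consumer_module(self, guild: int) -> int:
        """The module that catabolises guild ``guild``'s secreted by-product."""
        return 2 * guild + 1

    def resource_module(self, family: int) -> int:
        return 2 * self.n_guilds + family


@dataclass
class Community:
    """A synthetic reaction pool plus organisms with trait annotations."""

    pool: ReactionPool
    organisms: list[ReactionSet]
    config: GeneratorConfig
    guild_of: dict[str, int] = field(default_factory=dict)
    resource_of: dict[str, int] = field(default_factory=dict)
    habitat_of: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.pool, self.organisms))


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators spawned from one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_community(config: GeneratorConfig) -> Community:
    """Sample a reaction pool and trait-annotated organisms.

    A member of guild g preferring substrate family f in habitat m carries
    the whole blocks ``P_g``, ``C_{g-1}``, ``R_f`` and ``H_m``, plus a
    Poisson-sized background draw from the non-module region, targeting
    ``mean_reactions`` reactions per organism overall.
    """
    rng_bg, rng_roles = _streams(config.seed, 4)[:2]
    width = len(str(config.pool_size))
    pool_ids = [f"RXN{i:0{width}d}" for i in range(config.pool_size)]

    background_slots = np.arange(config.module_region, config.pool_size)
    mean_background = config.mean_reactions - (3 * config.module_size + config.habitat_size)

    organisms: list[ReactionSet] = []
    guild_of: dict[str, int] = {}
    resource_of: dict[str, int] = {}
    habitat_of: dict[str, int] = {}
    org_width = len(str(config.n_organisms))
    for i in range(config.n_organisms):
        org_id = f"ORG{i:0{org_width}d}"
        guild = int(rng_roles.integers(config.n_guilds))
        resource = int(rng_roles.integers(config.n_resources))
        habitat = int(rng_roles.integers(config.n_habitats))
        n_bg = int(np.clip(rng_bg.poisson(mean_background), 1, len(background_slots)))
        chosen = rng_bg.choice(background_slots, size=n_bg, replace=False)
        indices = set(chosen.tolist())
        indices.update(config.module_block(config.producer_module(guild)))
        indices.update(config.module_block(
            config.consumer_module((guild - 1) % config.n_guilds)))
        indices.update(config.module_block(config.resource_module(resource)))
        indices.update(config.habitat_block(habitat))
        organisms.append(ReactionSet(org_id, frozenset(pool_ids[j] for j in indices)))
        guild_of[org_id] = guild
        resource_of[org_id] = resource
        habitat_of[org_id] = habitat

    return Community(ReactionPool(pool_ids), organisms, config,
                     guild_of, resource_of, habitat_of)


def plant_interactions(
    community: Community, config: GeneratorConfig | None = None
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Plant labelled pairs into a community.

    Returns ``(records, truth)``: the records carry labels flipped with
    probability ``eta``; the truth list carries the planted labels.
    """
    config = config or community.config
    rng_pairs, rng_noise = _streams(config.seed, 4)[2:4]
    n_org = len(community.organisms)
    n_pairs = config.n_cf + config.n_co
    if n_pairs > n_org * (n_org - 1) // 2:
        raise ValidationError("requested pairs exceed C(n_organisms, 2)")

    ids = [org.organism_id for org in community.organisms]
    guilds = np.array([community.guild_of[i] for i in ids])
    resources = np.array([community.resource_of[i] for i in ids])
    habitats = np.array([community.habitat_of[i] for i in ids])
    G = config.n_guilds
    all_ix = np.arange(n_org)
    chosen: set[tuple[int, int]] = set()

    cycle_dist = (guilds[None, :] - guilds[:, None]) % G
    feeds = cycle_dist == 1                        # row produces for column
    overlaps = (resources[None, :] == resources[:, None]) & \
        (cycle_dist != 0) & (cycle_dist != 1) & (cycle_dist != G - 1)
    cooccur = habitats[None, :] == habitats[:, None]

    def pick(a: int, mask_row: np.ndarray) -> int | None:
        candidates = [int(b) for b in all_ix[mask_row & (all_ix != a)]
                      if (min(a, b), max(a, b)) not in chosen]
        if not candidates:
            return None
        return int(rng_pairs.choice(candidates))

    def draw_pair(kind: str) -> tuple[int, int]:
        # structured pairs prefer co-occurring partners; the habitat constraint
        # is dropped only once no habitat offers an eligible fresh pair
        tiers = (True, False) if kind in ("cf", "co") else (False,)
        for within_habitat in tiers:
            for a in rng_pairs.permutation(n_org):
                a = int(a)
                if kind == "cf":
                    scope = cooccur[a] if within_habitat else np.ones(n_org, bool)
                    b = pick(a, feeds[a] & scope)       # a feeds b
                    if b is not None:
                        return a, b
                    b = pick(a, feeds[:, a] & scope)    # b feeds a: swap roles
                    if b is not None:
                        return b, a
                elif kind == "co":
                    scope = cooccur[a] if within_habitat else np.ones(n_org, bool)
                    b = pick(a, overlaps[a] & scope)
                    if b is not None:
                        return a, b
                else:
                    b = pick(a, all_ix != a)
                    if b is not None:
                        return a, b
        raise ValidationError(
            f"could not draw a fresh {kind} pair; community too small for the requested counts"
        )

    def plant(kind: str) -> tuple[int, int]:
        a, b = draw_pair(kind)
        chosen.add((min(a, b), max(a, b)))
        return a, b

    truth: list[InteractionRecord] = []
    for label, count, strength in ((CROSS_FEEDING, config.n_cf, config.alpha),
                                   (COMPETITION, config.n_co, config.beta)):
        kind = "cf" if label == CROSS_FEEDING else "co"
        for _ in range(count):
            structured = rng_pairs.random() < strength
            a, b = plant(kind if structured else "random")
            truth.append(InteractionRecord(ids[a], ids[b], label))

    records: list[InteractionRecord] = []
    flips = rng_noise.random(len(truth)) < config.eta
    for rec, flip in zip(truth, flips):
        label = rec.label
        if flip:
            label = COMPETITION if label == CROSS_FEEDING else CROSS_FEEDING
        records.append(InteractionRecord(rec.organism_a, rec.organism_b, label))
    return records, truth


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[PairDataset, list[InteractionRecord], list[InteractionRecord], Community]:
    """Generate, plant and encode in one call.

    Returns (augmented dataset, noisy records, planted truth, community).
    """
    community = generate_community(config)
    records, truth = plant_interactions(community, config)
    pool = build_reaction_pool(community.pool.reactions, community.organisms)
    profiles = {org.organism_id: encode_profile(org, pool) for org in community.organisms}
    dataset = augment_dataset(records, profiles, pool)
    return dataset, records, truth, community


#: Named study conditions.  ``tiny`` is for unit tests, ``paper_scale``
#: mirrors the real collection's dimensions, ``null`` has uninformative labels.
PRESETS: dict[str, GeneratorConfig] = {
    "tiny": GeneratorConfig(
        pool_size=50, n_organisms=12, mean_reactions=18,
        n_guilds=4, n_resources=2, module_size=2, n_habitats=2, habitat_size=4,
        n_cf=16, n_co=4, seed=7,
    ),
    "paper_scale": GeneratorConfig(seed=7),
    "null": GeneratorConfig(
        pool_size=800, n_organisms=120, mean_reactions=200,
        n_guilds=4, n_resources=3, module_size=20, n_habitats=4, habitat_size=50,
        n_cf=397, n_co=103, eta=0.5, seed=7,
    ),
}


def make_fixture(preset: str, out_dir, seed: int | None = None) -> dict[str, Path]:
    """Write a complete on-disk dataset bundle for a named preset.

    Emits the same formats the real pipeline consumes: a pool file, one
    reaction list per organism under ``networks/``, an interaction TSV, and a
    truth TSV with the planted (pre-noise) labels.
    """
    from . import io as io_formats

    try:
        config = PRESETS[preset]
    except KeyError:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}") from None
    if seed is not None:
        config = replace(config, seed=seed)

    out_dir = Path(out_dir)
    networks = out_dir / "networks"
    networks.mkdir(parents=True, exist_ok=True)
    community = generate_community(config)
    records, truth = plant_interactions(community, config)

    pool_path = out_dir / "pool.txt"
    pool_path.write_text("\n".join(community.pool.reactions) + "\n")
    for org in community.organisms:
        io_formats.write_reaction_list(org, networks / f"{org.organism_id}.txt")
    interactions_path = out_dir / "interactions.tsv"
    io_formats.write_interaction_table(records, interactions_path)
    truth_path = out_dir / "truth.tsv"
    io_formats.write_interaction_table(truth, truth_path)
    return {
        "pool": pool_path,
        "networks": networks,
        "interactions": interactions_path,
        "truth": truth_path,
    }
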