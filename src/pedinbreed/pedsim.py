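"""Synthetic livestock pedigrees: factorial-mating growth designs and
small random pedigrees for property testing.

The preset designs mate a fixed dam pool to a sire pool under a factorial
scheme (two litters per dam, different sires), grow the per-generation
census linearly for the first generations and then plateau, and each
generation replace the oldest fraction of breeding animals with the
highest-ranked young candidates from the previous generation.  The census
is fully determined by the design, so pedigree sizes are checkable in
closed form (:func:`expected_total_animals`) independently of the
generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import pedio
from .errors import ValidationError
from .pedio import PedRecord, Pedigree, RawPedigree

#: family size -> number of base sires (dam pool is fixed at 50,000).
_PRESET_BASE_SIRES = {1000: 100, 200: 500, 4: 25000}


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulation scenario.

    The per-generation census is ``gen1_size + growth_per_gen * (g - 1)``
    capped at ``plateau_size``; the active sire pool scales with the
    census so the half-sib family size ``gen1_size / n_base_sires`` stays
    constant across generations.
    """

    n_base_sires: int
    n_base_dams: int = 50000
    gen1_size: int = 100000
    growth_per_gen: int = 50000
    plateau_size: int = 300000
    n_generations: int = 35
    litters_per_dam: int = 2
    litter_size: int = 1
    sire_replacement: float = 0.5
    dam_replacement: float = 0.3
    heritability: float = 0.3
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_base_sires < 2:
            raise ValidationError("need at least 2 base sires")
        if self.gen1_size % self.n_base_sires:
            raise ValidationError("gen1_size must be a multiple of n_base_sires")
        per_dam = self.litters_per_dam * self.litter_size
        if self.gen1_size != self.n_base_dams * per_dam:
            raise ValidationError(
                "gen1_size must equal n_base_dams * litters_per_dam * litter_size"
            )
        if not (0 < self.heritability <= 1):
            raise ValidationError("heritability must lie in (0, 1]")

    @property
    def family_size(self) -> int:
        return self.gen1_size // self.n_base_sires

    @property
    def base_size(self) -> int:
        return self.n_base_sires + self.n_base_dams

    def generation_size(self, g: int) -> int:
        if g < 1:
            raise ValidationError("generation index must be >= 1")
        return min(self.gen1_size + self.growth_per_gen * (g - 1),
                   self.plateau_size)

    def n_sires(self, g: int) -> int:
        return self.n_base_sires * self.generation_size(g) // self.gen1_size

    def n_dams(self, g: int) -> int:
        return self.generation_size(g) // (self.litters_per_dam * self.litter_size)

    def scaled(self, divisor: int) -> "SimDesign":
        """Shrink every census field by ``divisor`` (family size preserved)."""
        fields = ("n_base_sires", "n_base_dams", "gen1_size",
                  "growth_per_gen", "plateau_size")
        for name in fields:
            if getattr(self, name) % divisor:
                raise ValidationError(f"{name} not divisible by {divisor}")
        return dataclasses.replace(
            self, **{name: getattr(self, name) // divisor for name in fields}
        )


def design_from_family_size(
    family_size: int, n_generations: int = 35, seed: int = 0
) -> SimDesign:
    """Preset scenario for half-sib family sizes 1000, 200 or 4."""
    if family_size not in _PRESET_BASE_SIRES:
        raise ValidationError(
            f"unsupported family size {family_size}; "
            f"choose from {sorted(_PRESET_BASE_SIRES)}"
        )
    return SimDesign(
        n_base_sires=_PRESET_BASE_SIRES[family_size],
        n_generations=n_generations,
        seed=seed,
    )


def expected_total_animals(design: SimDesign, through_generation: int) -> int:
    """Closed-form pedigree size: base population + census of generations
    1..``through_generation`` (no simulation involved)."""
    if not (0 <= through_generation <= design.n_generations):
        raise ValidationError("through_generation out of range")
    return design.base_size + sum(
        design.generation_size(g) for g in range(1, through_generation + 1)
    )


@dataclass
class SimOutcome:
    """Generated pedigree as flat arrays (index = animal - 1).

    Base animals have generation 0 and unknown (-1) parents; every other
    animal has both parents from strictly earlier generations.  ``census``
    holds per-generation sizes, index 0 being the base population.
    """

    design: SimDesign
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    male: np.ndarray
    tbv: np.ndarray
    phen: np.ndarray
    census: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.sire.shape[0])

    def to_raw_pedigree(self) -> RawPedigree:
        """Standard record form; birth year = generation number."""
        records = [
            PedRecord(
                str(i + 1),
                None if self.sire[i] < 0 else str(self.sire[i] + 1),
                None if self.dam[i] < 0 else str(self.dam[i] + 1),
                int(self.generation[i]),
            )
            for i in range(self.n_total)
        ]
        return RawPedigree(records)

    def write_pedigree(self, path, delimiter: str = "\t") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i in range(self.n_total):
                fh.write(
                    f"{i + 1}{delimiter}{self.sire[i] + 1}"
                    f"{delimiter}{self.dam[i] + 1}"
                    f"{delimiter}{self.generation[i]}\n"
                )

    def to_pedigree(self, gamma: float = 0.0) -> Pedigree:
        """LAP-sorted pedigree with one shared metafounder for the base."""
        return pedio.pedigree_from_parent_indices(self.sire, self.dam, gamma)


def _select(candidates: np.ndarray, phen: np.ndarray, need: int) -> np.ndarray:
    """Top-``need`` candidates by phenotype (stable, ties by lowest id)."""
    order = np.argsort(-phen[candidates], kind="stable")
    return np.sort(candidates[order[:need]])


def simulate_pedigree(design: SimDesign, rng=None) -> SimOutcome:
    """Run the mating/growth/replacement design; reproducible from seed.

    The per-generation census is forced to the closed-form schedule: the
    active dam pool is sized to ``census / litters_per_dam`` each
    generation, every active dam produces one progeny per litter, and
    litters of the same dam get distinct sires (factorial mating).
    Selection uses the phenotype of a heritability-``h2`` trait as the
    breeding-value proxy.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    G = design.n_generations
    if design.n_sires(1) != design.n_base_sires or design.n_dams(1) != design.n_base_dams:
        raise ValidationError("generation-1 census incompatible with base pools")
    total = expected_total_animals(design, G)
    sire = np.full(total, -1, dtype=np.int64)
    dam = np.full(total, -1, dtype=np.int64)
    generation = np.zeros(total, dtype=np.int32)
    male = np.zeros(total, dtype=bool)
    tbv = np.empty(total, dtype=np.float64)
    phen = np.empty(total, dtype=np.float64)

    h2 = design.heritability
    sigma_e = np.sqrt((1.0 - h2) / h2) if h2 < 1 else 0.0
    s0, d0 = design.n_base_sires, design.n_base_dams
    nb = s0 + d0
    male[:s0] = True
    tbv[:nb] = rng.standard_normal(nb)
    phen[:nb] = tbv[:nb] + sigma_e * rng.standard_normal(nb)

    active_sires = np.arange(s0, dtype=np.int64)  # oldest first
    active_dams = np.arange(s0, nb, dtype=np.int64)
    census = [nb]
    ptr = nb
    prev_start, prev_stop = 0, nb
    for g in range(1, G + 1):
        t_sires, t_dams = design.n_sires(g), design.n_dams(g)
        if g > 1:
            prev = np.arange(prev_start, prev_stop, dtype=np.int64)
            for pool_name, pool, target, frac, want_male in (
                ("sire", active_sires, t_sires, design.sire_replacement, True),
                ("dam", active_dams, t_dams, design.dam_replacement, False),
            ):
                n_rm = int(frac * pool.shape[0])
                keep = pool[n_rm:]
                if keep.shape[0] > target:  # shrinking design: drop more oldest
                    keep = keep[keep.shape[0] - target :]
                need = target - keep.shape[0]
                cand = prev[male[prev] == want_male]
                if need > cand.shape[0]:
                    raise ValidationError(
                        f"design infeasible: need {need} replacement "
                        f"{pool_name}s but only {cand.shape[0]} candidates"
                    )
                recruits = _select(cand, phen, need)
                merged = np.concatenate([keep, recruits])
                if want_male:
                    active_sires = merged
                else:
                    active_dams = merged
        n_mothers = active_dams.shape[0]
        n_s = active_sires.shape[0]
        if n_s < design.litters_per_dam:
            raise ValidationError("fewer active sires than litters per dam")
        # factorial mating: litters_per_dam distinct sires per dam
        picks = np.empty((design.litters_per_dam, n_mothers), dtype=np.int64)
        picks[0] = rng.integers(0, n_s, n_mothers)
        for lit in range(1, design.litters_per_dam):
            # shifted draw guarantees distinctness from the first pick
            picks[lit] = (picks[0] + rng.integers(1, n_s, n_mothers)) % n_s
            if lit >= 2:
                while True:
                    clash = picks[lit] == picks[lit - 1]
                    if not clash.any():
                        break
                    picks[lit, clash] = (
                        picks[0][clash] + rng.integers(1, n_s, int(clash.sum()))
                    ) % n_s
        m = design.litters_per_dam * n_mothers * design.litter_size
        if m != design.generation_size(g):
            raise ValidationError("census arithmetic violated")  # pragma: no cover
        new = np.arange(ptr, ptr + m, dtype=np.int64)
        sires_g = active_sires[picks.reshape(-1)]
        dams_g = np.tile(active_dams, design.litters_per_dam)
        sires_g = np.repeat(sires_g, design.litter_size)
        dams_g = np.repeat(dams_g, design.litter_size)
        sire[new] = sires_g
        dam[new] = dams_g
        generation[new] = g
        male[new] = rng.random(m) < design.sex_ratio
        tbv[new] = 0.5 * (tbv[sires_g] + tbv[dams_g]) + np.sqrt(0.5) * rng.standard_normal(m)
        phen[new] = tbv[new] + sigma_e * rng.standard_normal(m)
        census.append(m)
        prev_start, prev_stop = ptr, ptr + m
        ptr += m
    return SimOutcome(
        design=design,
        sire=sire,
        dam=dam,
        generation=generation,
        male=male,
        tbv=tbv,
        phen=phen,
        census=np.array(census, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# random pedigrees for property testing


def random_pedigree(
    n: int,
    rng,
    p_unknown: float = 0.3,
    n_levels: int = 8,
    base_year: int = 2000,
) -> RawPedigree:
    """Small random pedigree with inbreeding loops and unknown parents.

    Animals are arranged in ``n_levels`` year layers; each non-base animal
    draws each parent slot independently from any earlier layer (or leaves
    it unknown with probability ``p_unknown``), which produces half-sib and
    full-sib loops.  Birth year = base_year + layer, so metafounder
    assignment by year bin yields several metafounders.
    """
    if n < 2:
        raise ValidationError("random pedigree needs at least 2 animals")
    level = (np.arange(n) * n_levels) // n
    records: list[PedRecord] = []
    for i in range(n):
        lo = int(np.searchsorted(level, level[i]))  # first animal of own level
        parents: list[str | None] = []
        for _ in range(2):
            if lo == 0 or rng.random() < p_unknown:
                parents.append(None)
            else:
                parents.append(str(int(rng.integers(0, lo)) + 1))
        records.append(
            PedRecord(str(i + 1), parents[0], parents[1],
                      base_year + int(level[i]))
        )
    return RawPedigree(records)
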