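"""Synthetic flock generator.

Emulates the study design behind the methane/maternal-trait analysis: sire
families with ~10 chamber-measured progeny each (2 measurement rounds x 2
days in respiration chambers), several thousand female relatives with
repeated adult-ewe records at ages 2-6, multi-flock multi-year contemporary
groups, and record-filter violations (broken chamber seals, feed refusals)
at configurable rates.  Default true variance components are back-solved
from the published phenotypic SDs, heritabilities and repeatabilities of
the source population, so the generator's defaults are the study
conditions, not tuning knobs.

Breeding values are generated by Mendelian sampling down the pedigree
(founders ~ N(0, G); offspring = parent average + a deviation with variance
(0.5 - 0.25(F_s + F_d)) G), which reproduces cov(a) = A (x) G exactly,
including under inbreeding, in O(n).

Chamber records are composed backwards from the simulated g CH4/day trait:
the raw columns (ch4_g, co2_g, dmi_kg, offered_kg, seal_ok) are constructed
so that the traits module re-derives the intended values.  The derived
ratio traits (CH4/DMI and the molar fraction) therefore only approximately
follow the generating model; exact-model data for parameter-recovery work
come from :func:`simulate_repeatability_records`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import Pedigree, _mendelian_variance


class SimulationError(ValueError):
    """Impossible simulation design (e.g. more sires than candidates)."""


@dataclass
class TraitTruth:
    """Generating parameters of one trait under the repeatability model."""

    mean: float
    sigma2_a: float
    sigma2_pe: dict[str, float] = field(default_factory=dict)
    sigma2_e: float = 1.0

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + sum(self.sigma2_pe.values()) + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.sigma2_p

    @property
    def repeatability(self) -> float:
        return (self.sigma2_a + sum(self.sigma2_pe.values())) / self.sigma2_p


def _default_traits() -> dict[str, TraitTruth]:
    """Per-trait components back-solved from published sigma_p, h2, repeatability.

    E.g. CH4 g/d: sigma_p = 2.99 so sigma2_p = 8.94; h2 = 0.26 gives
    sigma2_a = 2.32; repeatability 0.42 gives total PE = 1.43 (split between
    the within-round and across-round terms, an arbitrary split the source
    does not report); the residual is the remainder, 5.19.
    """
    return {
        "ch4": TraitTruth(24.0, 2.32, {"wgpe": 0.43, "agpe": 1.00}, 5.19),
        "lw": TraitTruth(67.3, 22.52, {"pe": 10.11}, 13.33),
        "bcs": TraitTruth(3.57, 0.0480, {"pe": 0.0192}, 0.1729),
        "fleece": TraitTruth(4.13, 0.2570, {"pe": 0.0523}, 0.1263),
        "fec": TraitTruth(6.07, 0.2060, {}, 0.4181),
        "nem": TraitTruth(4.30, 0.0908, {}, 0.2117),
        "pregsc": TraitTruth(1.94, 0.0415, {"pe": 0.0207}, 0.4562),
        "nlb": TraitTruth(1.91, 0.0403, {"pe": 0.0202}, 0.4436),
        "surv": TraitTruth(0.78, 0.0058, {"pe": 0.0069}, 0.1029),
    }


#: Default true genetic correlations of each trait with CH4 g/d (the anchor
#: trait); other pairs uncorrelated.  Values follow the published estimates.
_DEFAULT_RG_WITH_CH4 = {
    "lw": 0.77,
    "bcs": 0.35,
    "fleece": -0.10,
    "fec": 0.18,
    "nem": 0.01,
    "pregsc": -0.05,
    "nlb": -0.07,
    "surv": -0.20,
}

_TRAIT_ORDER = ["ch4", "lw", "bcs", "fleece", "fec", "nem", "pregsc", "nlb", "surv"]


@dataclass
class SimConfig:
    """Design knobs and true parameters of the synthetic flock.

    Defaults mirror the study design shrunk roughly tenfold: ~220
    chamber-measured progeny from 22 sires, ~790 adult ewes with repeated
    records at ages 2-6 across 2 flocks, with seal-break and feed-refusal
    records injected for filter testing.  Contemporary-group effect
    magnitudes are not reported for the real flocks; the defaults here are
    order-of-magnitude choices.
    """

    seed: int = 0
    n_sires: int = 22
    progeny_per_sire: int = 10
    daughters_per_sire: int = 36
    n_generations: int = 1
    n_birth_years: int = 2
    n_flocks: int = 2
    rounds: int = 2
    days_per_round: int = 2
    group_size: int = 24
    groups_per_lot: int = 4
    ewe_ages: tuple[int, ...] = (2, 3, 4, 5, 6)
    ewe_record_rate: float = 0.8
    n_mobs: int = 2
    seal_break_rate: float = 0.02
    refusal_rate: float = 0.05
    missing_rate: float = 0.01
    cg_sd_chamber: float = 1.5  # g/d, SD of contemporary-group effects
    cg_sd_maternal: float = 0.3  # as a fraction of each trait's phenotypic SD
    bdev_slope: float = 0.02  # g/d per day of birth-date deviation
    bdev_sd: float = 10.0  # days
    traits: dict[str, TraitTruth] = field(default_factory=_default_traits)
    rg_with_ch4: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RG_WITH_CH4)
    )
    assign_lines: bool = True  # rank sires by true CH4 merit into low/high lines

    def genetic_covariance(self) -> np.ndarray:
        """Build the full PSD genetic covariance matrix across traits."""
        k = len(_TRAIT_ORDER)
        g = np.zeros((k, k))
        sds = np.array([math.sqrt(self.traits[t].sigma2_a) for t in _TRAIT_ORDER])
        for i in range(k):
            g[i, i] = sds[i] ** 2
        for j, t in enumerate(_TRAIT_ORDER[1:], start=1):
            r = self.rg_with_ch4.get(t, 0.0)
            g[0, j] = g[j, 0] = r * sds[0] * sds[j]
        ssq = sum(v**2 for v in self.rg_with_ch4.values())
        if ssq > 1.0:
            raise SimulationError(
                "genetic correlations with CH4 imply a non-PSD covariance "
                f"(sum of squares {ssq:.3f} > 1)"
            )
        return g


@dataclass
class SimData:
    """Output tables of one simulated flock plus the generating truth."""

    chamber: pd.DataFrame
    maternal: pd.DataFrame
    eggs: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------


def _build_flock(config: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Deterministic flock structure: pedigree plus per-animal metadata.

    Roles: founder sires ("sire"), founder dams ("dam"), chamber-measured
    progeny ("chamber"), adult ewes ("ewe").  Chamber progeny and ewes are
    paternal half-sib sets of the same sires, so maternal traits correlate
    with methane only through pedigree links, as in the study.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    triples: list[tuple[str, str | None, str | None]] = []
    meta_rows: list[dict] = []
    counter = [0]

    def new_id(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]:06d}"

    def add_animal(aid, sire, dam, sex, role, byr, flk, gen):
        triples.append((aid, sire, dam))
        meta_rows.append(
            dict(animal=aid, sire=sire, sex=sex, role=role, byr=byr, flk=flk, generation=gen)
        )

    prev_males: list[str] = []
    sires_by_gen: dict[int, list[str]] = {}
    for gen in range(1, config.n_generations + 1):
        if gen == 1:
            sires = [new_id("S") for _ in range(config.n_sires)]
            for i, s in enumerate(sires):
                add_animal(s, None, None, "M", "sire", 0, i % config.n_flocks, 0)
        else:
            if len(prev_males) < config.n_sires:
                raise SimulationError(
                    f"generation {gen}: {config.n_sires} sires requested but only "
                    f"{len(prev_males)} male candidates available"
                )
            sires = list(rng.choice(prev_males, size=config.n_sires, replace=False))
        sires_by_gen[gen] = sires
        males_this_gen: list[str] = []
        for si, s in enumerate(sires):
            n_off = config.progeny_per_sire + config.daughters_per_sire
            for k in range(n_off):
                d = new_id("D")
                add_animal(d, None, None, "F", "dam", 0, si % config.n_flocks, 0)
                aid = new_id("P" if k < config.progeny_per_sire else "E")
                sex = ("M" if rng.random() < 0.5 else "F") if k < config.progeny_per_sire else "F"
                role = "chamber" if k < config.progeny_per_sire else "ewe"
                byr = int(rng.integers(0, config.n_birth_years)) + gen * 10
                flk = si % config.n_flocks
                add_animal(aid, s, d, sex, role, byr, flk, gen)
                if sex == "M":
                    males_this_gen.append(aid)
        prev_males = males_this_gen

    # only the last generation is chamber-measured / recorded as ewes
    last_gen = config.n_generations
    meta = pd.DataFrame(meta_rows)
    meta.loc[(meta.generation < last_gen) & meta.role.isin(["chamber", "ewe"]), "role"] = (
        "ancestor"
    )
    ped = Pedigree.from_triples(triples)
    meta = meta.set_index("animal", drop=False).loc[ped.ids].reset_index(drop=True)
    return ped, meta


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation sire-family pedigree under the given design."""
    return _build_flock(config)[0]


def simulate_breeding_values(
    ped: Pedigree, G: float | np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Additive genetic values with cov = A (x) G, by Mendelian sampling.

    Founders draw from N(0, G); an offspring gets the mean of its known
    parents' values plus a deviation with variance d_i * G, where d_i is
    the Mendelian-sampling fraction (1 for unknown parents, down to
    0.5 - 0.25(F_s + F_d) for two known parents), so the marginal variance
    is exact at every level of inbreeding.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = np.atleast_2d(np.asarray(G, dtype=float))
    nt = g.shape[0]
    eigvals = np.linalg.eigvalsh(g)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        raise SimulationError("genetic covariance matrix G is not PSD")
    try:
        l = np.linalg.cholesky(g)
    except np.linalg.LinAlgError:  # singular PSD: eigen square root
        w, v = np.linalg.eigh(g)
        l = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    n = len(ped)
    a = np.zeros((n, nt))
    z = rng.standard_normal((n, nt))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        mean = np.zeros(nt)
        if s >= 0:
            mean += 0.5 * a[s]
        if d >= 0:
            mean += 0.5 * a[d]
        di = _mendelian_variance(i, ped.sire, ped.dam, ped.f)
        a[i] = mean + math.sqrt(di) * (z[i] @ l.T)
    return a if np.asarray(G).ndim == 2 else a[:, 0]


# ---------------------------------------------------------------------------
# record tables
# ---------------------------------------------------------------------------


def simulate_records(ped: Pedigree, config: SimConfig) -> SimData:
    """Generate chamber, maternal and egg-count tables for a simulated flock.

    Record value = contemporary-group effect + covariate effect + breeding
    value + permanent-environment draws + residual, per the repeatability
    model; chamber rows are back-composed into raw gas/intake columns and
    include injected seal breaks and feed refusals for filter testing.
    """
    _, meta = _build_flock(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    g = config.genetic_covariance()
    bv = simulate_breeding_values(ped, g, rng)
    bv_of = {aid: bv[i] for i, aid in enumerate(ped.ids)}
    t_ix = {t: i for i, t in enumerate(_TRAIT_ORDER)}

    chamber = _chamber_table(config, meta, bv_of, t_ix, rng)
    maternal = _maternal_table(config, meta, bv_of, t_ix, rng)
    eggs = _egg_table(config, meta, bv_of, t_ix, rng)

    truth = {
        "seed": config.seed,
        "traits": {k: asdict(v) for k, v in config.traits.items()},
        "rg_with_ch4": dict(config.rg_with_ch4),
        "n_chamber_animals": int((meta.role == "chamber").sum()),
        "n_ewes": int((meta.role == "ewe").sum()),
    }
    return SimData(chamber=chamber, maternal=maternal, eggs=eggs, truth=truth)


def _cg_effects(levels: pd.Series, sd: float, rng) -> np.ndarray:
    uniq = pd.unique(levels)
    draw = {lv: rng.normal(0.0, sd) for lv in uniq}
    return np.array([draw[lv] for lv in levels])


def _chamber_table(config, meta, bv_of, t_ix, rng) -> pd.DataFrame:
    tt = config.traits["ch4"]
    animals = meta.loc[meta.role == "chamber"]
    # screening-based line assignment: sires ranked by true CH4 merit,
    # bottom half founding the low-methane line
    line_of: dict[str, str] = {}
    if config.assign_lines and len(animals):
        sire_bv = {
            s: bv_of[s][t_ix["ch4"]] for s in animals.sire.dropna().unique()
        }
        median = float(np.median(list(sire_bv.values())))
        line_of = {s: ("low" if v <= median else "high") for s, v in sire_bv.items()}
    rows = []
    pe_w_draw: dict[tuple, float] = {}
    pe_y_draw: dict[str, float] = {}
    sd_w = math.sqrt(tt.sigma2_pe.get("wgpe", 0.0))
    sd_y = math.sqrt(tt.sigma2_pe.get("agpe", 0.0))
    bdev = {a: rng.normal(0.0, config.bdev_sd) for a in animals.animal}
    # birth/rearing rank recorded as a factor (no simulated effect);
    # separate stream so the phenotype draws are unchanged by its presence
    rng_brr = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    brr = {
        a: int(rng_brr.choice([11, 21, 22], p=[0.3, 0.35, 0.35]))
        for a in animals.animal
    }
    order = animals.reset_index(drop=True)
    lot_size = config.group_size * config.groups_per_lot
    for pos, rec in enumerate(order.itertuples()):
        a = rec.animal
        lot = pos // lot_size
        group = (pos % lot_size) // config.group_size
        ryr = rec.byr + 1
        for rnd in range(1, config.rounds + 1):
            key_w = (a, rnd)
            if key_w not in pe_w_draw:
                pe_w_draw[key_w] = rng.normal(0.0, sd_w)
            if a not in pe_y_draw:
                pe_y_draw[a] = rng.normal(0.0, sd_y)
            for day in range(1, config.days_per_round + 1):
                rows.append(
                    dict(
                        animal=a,
                        byr=rec.byr,
                        flk=rec.flk,
                        sex=rec.sex,
                        brr=brr[a],
                        line=line_of.get(rec.sire, "unselected"),
                        ryr=ryr,
                        lot=lot,
                        group=group,
                        round=rnd,
                        day=day,
                        bdev=bdev[a],
                        pe=pe_w_draw[key_w] + pe_y_draw[a],
                    )
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cg1 = _cg_effects(
        df.byr.astype(str) + ":" + df.flk.astype(str) + ":" + df.sex,
        config.cg_sd_chamber,
        rng,
    )
    cg2 = _cg_effects(
        df.ryr.astype(str) + ":" + df.lot.astype(str) + ":" + df.group.astype(str)
        + ":" + df["round"].astype(str),
        config.cg_sd_chamber,
        rng,
    )
    a_eff = np.array([bv_of[a][t_ix["ch4"]] for a in df.animal])
    e = rng.normal(0.0, math.sqrt(tt.sigma2_e), len(df))
    ch4 = tt.mean + cg1 + cg2 + config.bdev_slope * df.bdev.to_numpy() + a_eff + df.pe.to_numpy() + e
    df = df.drop(columns=["pe"])

    # back-compose raw chamber columns so the traits module re-derives ch4
    lw = rng.normal(45.0, 5.0, len(df))
    offered = 0.04 * lw
    eaten_frac = rng.uniform(0.95, 1.0, len(df))
    refuse = rng.random(len(df)) < config.refusal_rate
    eaten_frac[refuse] = rng.uniform(0.5, 0.949, refuse.sum())
    frac_target = np.clip(rng.normal(0.059, 0.004, len(df)), 0.02, 0.12)
    mol_ch4 = np.maximum(ch4, 1e-3) / 16.04
    co2 = (mol_ch4 / frac_target - mol_ch4) * 44.01
    df["live_weight_kg"] = lw
    df["offered_kg"] = offered
    df["dmi_kg"] = offered * eaten_frac
    df["ch4_g"] = np.maximum(ch4, 1e-3)
    df["co2_g"] = co2
    df["seal_ok"] = rng.random(len(df)) >= config.seal_break_rate
    missing = rng.random(len(df)) < config.missing_rate
    df.loc[missing, "dmi_kg"] = np.nan
    return df


def _maternal_table(config, meta, bv_of, t_ix, rng) -> pd.DataFrame:
    ewes = meta.loc[meta.role == "ewe"].reset_index(drop=True)
    if ewes.empty:
        return pd.DataFrame()
    rng_fac = np.random.default_rng(np.random.SeedSequence([config.seed, 304]))
    brr = {
        a: int(rng_fac.choice([11, 21, 22], p=[0.3, 0.35, 0.35]))
        for a in ewes.animal
    }
    aod = {a: int(rng_fac.integers(2, 7)) for a in ewes.animal}
    pe_draw: dict[tuple[str, str], float] = {}

    def pe(a: str, trait: str, sd: float) -> float:
        key = (a, trait)
        if key not in pe_draw:
            pe_draw[key] = rng.normal(0.0, sd)
        return pe_draw[key]

    rows = []
    for rec in ewes.itertuples():
        a = rec.animal
        mob = int(rng.integers(0, config.n_mobs))
        nlb_prev = 0
        for age in config.ewe_ages:
            if rng.random() > config.ewe_record_rate:
                continue
            ryr = rec.byr + age
            ageclass = min(age, 5)  # ages 5 and 6 share a class
            row = dict(
                animal=a,
                rflk=rec.flk,
                ryr=ryr,
                mob=mob,
                ageclass=ageclass,
                nlb_prev=nlb_prev,
                brr=brr[a],
                aod=aod[a],
            )
            latents = {}
            for trait in ("lw", "bcs", "fleece", "pregsc", "nlb", "surv"):
                tt = config.traits[trait]
                sd_pe = math.sqrt(tt.sigma2_pe.get("pe", 0.0))
                val = (
                    tt.mean
                    + bv_of[a][t_ix[trait]]
                    + pe(a, trait, sd_pe)
                    + rng.normal(0.0, math.sqrt(tt.sigma2_e))
                )
                latents[trait] = val
            row["lw_mate_kg"] = latents["lw"]
            row["bcs_mate"] = float(np.clip(np.round(latents["bcs"] * 2) / 2, 1.0, 5.0))
            row["fleece_kg"] = max(latents["fleece"], 0.1)
            row["pregsc"] = int(np.clip(np.round(latents["pregsc"]), 0, 3))
            nlb = int(np.clip(np.round(latents["nlb"]), 0, 3))
            row["nlb"] = nlb
            p_surv = float(np.clip(latents["surv"], 0.0, 1.0))
            row["n_weaned"] = int(rng.binomial(nlb, p_surv)) if nlb > 0 else 0
            rows.append(row)
            nlb_prev = nlb
    df = pd.DataFrame(rows)
    # contemporary-group effects on the continuous traits
    cg_key = (
        df.rflk.astype(str) + ":" + df.ryr.astype(str) + ":" + df.mob.astype(str)
        + ":" + df.ageclass.astype(str)
    )
    for trait, col in (("lw", "lw_mate_kg"), ("fleece", "fleece_kg")):
        sd = config.cg_sd_maternal * math.sqrt(config.traits[trait].sigma2_p)
        df[col] = df[col] + _cg_effects(cg_key, sd, rng)
    return df


def _egg_table(config, meta, bv_of, t_ix, rng) -> pd.DataFrame:
    keep = meta.loc[meta.role.isin(["chamber", "ewe"])].reset_index(drop=True)
    rows = []
    for rec in keep.itertuples():
        a = rec.animal
        row = dict(animal=a, byr=rec.byr, flk=rec.flk, sex=rec.sex)
        for trait, col in (("fec", "fec_raw"), ("nem", "nem_raw")):
            tt = config.traits[trait]
            latent = (
                tt.mean + bv_of[a][t_ix[trait]] + rng.normal(0.0, math.sqrt(tt.sigma2_e))
            )
            row[col] = max(float(np.round(math.exp(latent) - 50.0)), 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact-model generator for parameter recovery
# ---------------------------------------------------------------------------


def simulate_repeatability_records(
    n_sires: int,
    progeny_per_sire: int,
    rounds: int = 2,
    days_per_round: int = 2,
    G: float | np.ndarray = 0.25,
    PE: float | np.ndarray = 0.15,
    E: float | np.ndarray = 0.60,
    cg_sd: float = 0.0,
    n_groups: int = 10,
    mean: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[Pedigree, pd.DataFrame]:
    """Balanced sire-family data following the repeatability model exactly.

    Each of ``n_sires`` unrelated sires gets ``progeny_per_sire`` progeny
    (dams unrelated founders); every progeny is recorded ``rounds x
    days_per_round`` times.  Scalar G/PE/E give one trait; 2x2 matrices give
    two traits co-recorded on every occasion (y1, y2 columns).  The PE term
    is at the animal level (across rounds).  Optional contemporary-group
    noise (``cg_sd``) is shared by records in the same group.

    Returns the pedigree and a tidy table with columns animal, sire, round,
    day, group and y (or y1, y2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = np.atleast_2d(np.asarray(G, dtype=float))
    pe_m = np.atleast_2d(np.asarray(PE, dtype=float))
    e_m = np.atleast_2d(np.asarray(E, dtype=float))
    nt = g.shape[0]

    triples = []
    for s in range(n_sires):
        sid = f"S{s:05d}"
        triples.append((sid, None, None))
        for k in range(progeny_per_sire):
            did = f"D{s:05d}_{k:03d}"
            triples.append((did, None, None))
            triples.append((f"P{s:05d}_{k:03d}", sid, did))
    ped = Pedigree.from_triples(triples)
    bv = simulate_breeding_values(ped, g, rng)  # (n, nt): g is always 2-D here

    l_pe = np.linalg.cholesky(pe_m + 1e-14 * np.eye(nt))
    l_e = np.linalg.cholesky(e_m + 1e-14 * np.eye(nt))
    rows = []
    values = []
    prog = [(i, a) for i, a in enumerate(ped.ids) if a.startswith("P")]
    cg = rng.normal(0.0, cg_sd, n_groups) if cg_sd > 0 else np.zeros(n_groups)
    for j, (i, a) in enumerate(prog):
        pe_i = rng.standard_normal(nt) @ l_pe.T
        grp = j % n_groups
        for rnd in range(1, rounds + 1):
            for day in range(1, days_per_round + 1):
                e_i = rng.standard_normal(nt) @ l_e.T
                values.append(mean + cg[grp] + bv[i] + pe_i + e_i)
                rows.append(
                    dict(animal=a, sire=ped.ids[ped.sire[i]], round=rnd, day=day, group=grp)
                )
    df = pd.DataFrame(rows)
    vals = np.asarray(values)
    if nt == 1:
        df["y"] = vals[:, 0]
    else:
        for t in range(nt):
            df[f"y{t + 1}"] = vals[:, t]
    return ped, df
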