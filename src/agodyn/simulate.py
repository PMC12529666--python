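"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates one of the study designs -- equilibrium titrations
(0-10 nM enzyme against ~0.1 nM target), dissociation chases (1-16 min),
association time courses (0.25-1.5 nM enzyme, 15-300 s), two-timepoint
RBNS pulls (30 s and 1 h), replicate small-RNA count tables, and
prediction/DE tables for network building -- and returns the data together
with a ground-truth dict sufficient to score recovery.

Determinism: every generator derives one pseudorandom stream from
(seed, scenario name), so identical arguments give identical outputs and
scenarios are independently reproducible.

The RBNS occupancy model is intentionally minimal: member m in class c is
pulled down with probability proportional to

    pool(m) * [w_c^phi * (1 - exp(-r t)) + b]

where w_c are class binding weights (8mer > 7mer-m8 > 7mer-A1 > 6mer;
the no-seed class has w = 0 so all background binding enters through b),
phi <= 1 is a seed-fidelity exponent (phi < 1 compresses the
class hierarchy, modeling mutant mis-targeting), r is a single scenario-
wide approach-to-equilibrium rate, and b a constant no-seed baseline.
Slow r plus large b reproduces the mutant pattern of low early fidelity
that improves with incubation time; it is a test harness, not a
biophysical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from agodyn import kinetics
from agodyn.isomirs import CanonicalMiRNA, categorize
from agodyn.seeds import GuideRNA, LibraryMember, SiteClass, classify_library, expand_degenerate

__all__ = [
    "MIR122_GUIDE",
    "RBNSLibraryConfig",
    "RBNSScenario",
    "WT_LIKE",
    "MUTANT_LIKE",
    "DECAY_WT_LIKE",
    "DECAY_MUTANT_LIKE",
    "gen_isotherm",
    "gen_dissociation",
    "gen_association",
    "gen_rbns",
    "gen_smallrna",
    "gen_network_data",
]

#: miRBase hsa-miR-122-5p; its g2-g8 seed is GGAGUGU (8mer target ACACUCCA).
MIR122_GUIDE = GuideRNA("miR-122", "UGGAGUGUGACAAUGGUGUUUG")


def _rng(seed: int, scenario: str) -> np.random.Generator:
    """One stream per (seed, scenario) so scenarios are independent."""
    return np.random.default_rng([int(seed), *scenario.encode()])


# --------------------------------------------------------------------------
# kinetics generators

def gen_isotherm(
    kd_nM: float = 0.05,
    bmax: float = 1.0,
    s_total_nM: float = 0.1,
    e_grid_nM=None,
    noise_sd: float = 0.03,
    seed: int = 0,
):
    """Noisy equilibrium titration from the ligand-depletion isotherm.

    The default grid spans 0-10 nM enzyme at 8 points around K_D.
    Returns (DataFrame[e_total_nM, fraction_bound], ground_truth).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if e_grid_nM is None:
        e_grid_nM = np.array([0.0, 0.01, 0.025, 0.05, 0.1, 0.5, 2.0, 10.0])
    e = np.asarray(e_grid_nM, dtype=float)
    f = kinetics.equilibrium_model(e, s_total_nM, kd_nM, bmax)
    rng = _rng(seed, "isotherm")
    f_obs = f + rng.normal(0.0, noise_sd, size=f.shape)
    data = pd.DataFrame({"e_total_nM": e, "fraction_bound": f_obs})
    truth = {"kd_nM": kd_nM, "bmax": bmax, "s_total_nM": s_total_nM, "noise_sd": noise_sd}
    return data, truth


@dataclass(frozen=True)
class DecayPreset:
    a_fast: float
    k_fast: float  # min^-1
    k_slow: float
    plateau: float = 0.0


#: fast single-phase release, as wild-type AGO2 shows
DECAY_WT_LIKE = DecayPreset(a_fast=1.0, k_fast=1.0, k_slow=1.0)
#: biphasic release with a ~20-fold slower second phase, as the severe mutants show
DECAY_MUTANT_LIKE = DecayPreset(a_fast=0.5, k_fast=1.0, k_slow=0.05)


def gen_dissociation(
    preset: DecayPreset = DECAY_MUTANT_LIKE,
    timepoints=None,
    noise_sd: float = 0.03,
    seed: int = 0,
):
    """Noisy two-phase decay time course (minutes), normalized to t = 0.

    Default time points cover 0-16 min.  The t = 0 observation is exactly 1
    at zero noise.
    """
    if timepoints is None:
        timepoints = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0])
    t = np.asarray(timepoints, dtype=float)
    f = kinetics.biexp_decay_model(t, preset.a_fast, preset.k_fast, preset.k_slow, preset.plateau)
    rng = _rng(seed, "dissociation")
    f_obs = f + rng.normal(0.0, noise_sd, size=f.shape)
    f_obs[t == 0] = f[t == 0] + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
    data = pd.DataFrame({"time_min": t, "fraction_bound": f_obs})
    truth = {
        "a_fast": preset.a_fast,
        "k_fast": preset.k_fast,
        "k_slow": preset.k_slow,
        "plateau": preset.plateau,
        "noise_sd": noise_sd,
    }
    return data, truth


#: fast, wild-type-like association; saturates within the first sampling
#: interval of the 15-300 s design, so k_obs is poorly constrained there
ASSOC_WT_KON = 0.2  # nM^-1 s^-1
#: ~5-fold slower, mutant-like association; resolvable on the same design
ASSOC_MUTANT_KON = 0.04  # nM^-1 s^-1


def gen_association(
    k_on: float = ASSOC_MUTANT_KON,  # nM^-1 s^-1
    k_off: float = 0.01,  # s^-1
    e_levels_nM=None,
    timepoints=None,
    noise_sd: float = 0.03,
    seed: int = 0,
):
    """Association time courses at several enzyme concentrations.

    Per level, F(t) = F_eq (1 - exp(-(k_on [E] + k_off) t)) with
    F_eq = k_on[E] / (k_on[E] + k_off).  Defaults emulate 0.25-1.5 nM
    enzyme and 15-300 s sampling.  Returns a long DataFrame
    (e_total_nM, time_s, fraction_bound) and the ground truth.
    """
    if e_levels_nM is None:
        e_levels_nM = np.array([0.25, 0.5, 0.75, 1.0, 1.5])
    if timepoints is None:
        timepoints = np.array([0.0, 15.0, 30.0, 60.0, 120.0, 180.0, 300.0])
    rng = _rng(seed, "association")
    frames = []
    for e in np.asarray(e_levels_nM, dtype=float):
        kobs = k_on * e + k_off
        feq = k_on * e / kobs
        f = feq * (1.0 - np.exp(-kobs * np.asarray(timepoints, dtype=float)))
        f_obs = f + rng.normal(0.0, noise_sd, size=f.shape)
        frames.append(
            pd.DataFrame(
                {"e_total_nM": e, "time_s": np.asarray(timepoints, float), "fraction_bound": f_obs}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    truth = {"k_on": k_on, "k_off": k_off, "noise_sd": noise_sd}
    return data, truth


# --------------------------------------------------------------------------
# RBNS generator

@dataclass(frozen=True)
class RBNSLibraryConfig:
    """Degenerate library layout plus the sequencing wrapper."""

    pattern: str = "RYRYYYYR"
    flank5: str = "CGAUACGC"
    flank3: str = "GUCAGUCG"
    adapter: str = "AGAUCGGAAGAGC"
    guide: GuideRNA = MIR122_GUIDE

    def members(self) -> list[LibraryMember]:
        return [
            LibraryMember(v, self.flank5, self.flank3) for v in expand_degenerate(self.pattern)
        ]


@dataclass(frozen=True)
class RBNSScenario:
    """Occupancy-model parameters for one protein sample."""

    name: str
    fidelity_phi: float  # 1 = full class hierarchy; < 1 compresses it
    baseline: float  # class-independent (no-seed) binding term
    rate: float  # approach-to-equilibrium rate, s^-1
    class_weights: dict[SiteClass, float] = field(
        default_factory=lambda: {
            SiteClass.EIGHT_MER: 400.0,
            SiteClass.SEVEN_MER_M8: 120.0,
            SiteClass.SEVEN_MER_A1: 80.0,
            SiteClass.SIX_MER: 20.0,
            # all no-seed binding is carried by the baseline term
            SiteClass.NONE: 0.0,
        }
    )

    def occupancy(self, site_class: SiteClass, t: float) -> float:
        w = self.class_weights[site_class]
        return w**self.fidelity_phi * (1.0 - np.exp(-self.rate * t)) + self.baseline


#: high-fidelity, fast-binding sample (wild-type-like)
WT_LIKE = RBNSScenario("wt", fidelity_phi=1.0, baseline=0.2, rate=0.05)
#: low-fidelity, slow-binding sample (severe-mutant-like)
MUTANT_LIKE = RBNSScenario("mutant", fidelity_phi=0.4, baseline=1.0, rate=0.004)


def gen_rbns(
    scenario: RBNSScenario = WT_LIKE,
    library: RBNSLibraryConfig | None = None,
    timepoints_s=(30.0, 3600.0),
    depth: int = 50_000,
    pool_alpha: float = 5.0,
    barcodes: dict[str, str] | None = None,
    seed: int = 0,
):
    """Raw RBNS reads for an input library and bound samples at each time.

    The input pool is a Dirichlet(alpha)-skewed multinomial over the 256
    members (synthesis bias); a bound sample at time t draws member m with
    probability proportional to pool(m) * occupancy(class(m), t).  Reads
    are wrapped as barcode + 5' flank + variable + 3' flank + adapter.

    Returns (reads_by_sample, barcode_map, ground_truth).  Sample names are
    ``input`` and ``<scenario>_<t>s``; exactly ``depth`` reads per sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    lib = library or RBNSLibraryConfig()
    members = lib.members()
    classes = classify_library(members, lib.guide, scan_mode="fixed-register")
    sample_names = ["input"] + [f"{scenario.name}_{int(t)}s" for t in timepoints_s]
    if barcodes is None:
        barcodes = _default_barcodes(sample_names)
    if set(barcodes.values()) != set(sample_names):
        raise ValueError("barcode map must cover exactly the generated samples")
    bc_of = {s: b for b, s in barcodes.items()}

    rng = _rng(seed, f"rbns:{scenario.name}")
    seqs = [m.variable for m in members]
    pool = rng.dirichlet(np.full(len(members), pool_alpha))

    def wrap(var: str, sample: str) -> str:
        return bc_of[sample] + lib.flank5 + var + lib.flank3 + lib.adapter

    reads: dict[str, list[str]] = {}
    member_draws = {}
    counts = rng.multinomial(depth, pool)
    member_draws["input"] = counts
    for t in timepoints_s:
        occ = np.array([scenario.occupancy(classes[v], t) for v in seqs])
        probs = pool * occ
        probs /= probs.sum()
        member_draws[f"{scenario.name}_{int(t)}s"] = rng.multinomial(depth, probs)
    for sample, cnt in member_draws.items():
        sample_reads = []
        for v, c in zip(seqs, cnt):
            sample_reads.extend([wrap(v, sample)] * int(c))
        perm = rng.permutation(len(sample_reads))
        reads[sample] = [sample_reads[i] for i in perm]

    truth = {
        "scenario": scenario.name,
        "fidelity_phi": scenario.fidelity_phi,
        "baseline": scenario.baseline,
        "rate": scenario.rate,
        "class_weights": {sc.label: w for sc, w in scenario.class_weights.items()},
        "pool": dict(zip(seqs, pool.tolist())),
        "member_counts": {s: dict(zip(seqs, c.tolist())) for s, c in member_draws.items()},
        "depth": depth,
        "timepoints_s": list(timepoints_s),
    }
    return reads, barcodes, truth


def _default_barcodes(samples: list[str]) -> dict[str, str]:
    """Deterministic 8-base barcodes, pairwise Hamming distance >= 4."""
    alphabet = ["AAAAGGGG", "CCCCUUUU", "AACCGGUU", "GGUUAACC", "AGAGCUCU", "CUCUAGAG"]
    if len(samples) > len(alphabet):
        raise ValueError("too many samples for the built-in barcode set")
    return {alphabet[i]: s for i, s in enumerate(samples)}


# --------------------------------------------------------------------------
# small-RNA generator

_ALPH = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPH, size=length))


def _mutate(rng: np.random.Generator, seq: str, off5: int, off3: int, n_mm: int) -> str:
    """Apply end offsets and internal substitutions to a canonical sequence."""
    s = seq
    if off5 < 0:
        s = s[-off5:]
    elif off5 > 0:
        s = _random_rna(rng, off5) + s
    if off3 < 0:
        s = s[: len(s) + off3]
    elif off3 > 0:
        s = s + _random_rna(rng, off3)
    s = list(s)
    # mutate only interior positions templated by the canonical
    lo, hi = max(off5, 0), len(s) - max(off3, 0)
    positions = rng.choice(np.arange(lo, hi), size=n_mm, replace=False)
    for p in positions:
        s[p] = rng.choice([c for c in "ACGU" if c != s[p]])
    return "".join(s)


#: (off5, off3, mismatches) recipes for planted non-canonical species
_VARIANT_RECIPES = {
    "3p-trimmed+exchange": (0, -2, 1),
    "3p-trimmed": (0, -1, 0),
    "3p-extended": (0, 1, 0),
    "3p-extended+exchange": (0, 1, 1),
    "nucleotide-exchange": (0, 0, 1),
    "5p-variant": (-1, 0, 0),
    "mixed": (1, -1, 1),
}


def gen_smallrna(
    n_precursors: int = 8,
    replicates: int = 3,
    n_exclusive: int = 10,
    exclusive_category_probs: dict[str, float] | None = None,
    flip_precursors: int = 2,
    arm_flip_log2: float = 3.0,
    base_mean: float = 200.0,
    nb_size: float = 10.0,
    conditions: tuple[str, str] = ("wt", "mutant"),
    seed: int = 0,
):
    """Replicate small-RNA count tables with planted effects.

    Emits a species x sample count table over canonical mature miRNAs (both
    arms of ``n_precursors`` precursors) plus planted isomiR species.
    Planted effects, all recorded in the ground truth:

    * ``n_exclusive`` isomiR species present (NB counts around
      ``base_mean``) in every replicate of the second condition and absent
      from the first, with categories drawn from
      ``exclusive_category_probs`` (default: half 3p-trimmed+exchange, the
      rest spread over the remaining categories, mirroring a 3'-remodeling
      phenotype);
    * an arm-ratio flip of ``arm_flip_log2`` (log2 units, toward 3p) in the
      second condition for the first ``flip_precursors`` precursors.

    Returns (counts DataFrame, canonicals, ground_truth).  Sample columns
    are ``<condition>_r<i>``.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate per condition")
    if exclusive_category_probs is None:
        exclusive_category_probs = {
            "3p-trimmed+exchange": 0.5,
            "3p-trimmed": 0.1,
            "3p-extended": 0.1,
            "3p-extended+exchange": 0.1,
            "nucleotide-exchange": 0.1,
            "mixed": 0.1,
        }
    rng = _rng(seed, "smallrna")
    canonicals: list[CanonicalMiRNA] = []
    for i in range(n_precursors):
        prec = f"mir-{i + 1:03d}"
        for arm in ("5p", "3p"):
            canonicals.append(
                CanonicalMiRNA(f"{prec}-{arm}", _random_rna(rng, 22), precursor=prec, arm=arm)
            )

    samples = [f"{cond}_r{i + 1}" for cond in conditions for i in range(replicates)]
    cond_of = {s: s.rsplit("_r", 1)[0] for s in samples}
    flipped = [f"mir-{i + 1:03d}" for i in range(flip_precursors)]

    def nb(mean: float, size: int = 1):
        return rng.negative_binomial(nb_size, nb_size / (nb_size + mean), size=size)

    rows: dict[str, list[int]] = {}
    meta: dict[str, dict] = {}
    for c in canonicals:
        mean = base_mean * float(rng.lognormal(0.0, 0.5))
        counts = []
        for s in samples:
            m = mean
            if c.precursor in flipped and cond_of[s] == conditions[1]:
                # shift reads toward the 3p arm, conserving the precursor total
                m = mean * 2 ** (arm_flip_log2 / 2 if c.arm == "3p" else -arm_flip_log2 / 2)
            counts.append(int(nb(m)[0]))
        rows[c.name] = counts
        meta[c.name] = {"kind": "canonical", "category": "canonical", "canonical": c.name}

    categories = list(exclusive_category_probs)
    probs = np.array([exclusive_category_probs[c] for c in categories])
    probs = probs / probs.sum()
    exclusive_names = []
    for j in range(n_exclusive):
        cat = str(rng.choice(categories, p=probs))
        off5, off3, mm = _VARIANT_RECIPES[cat]
        host = canonicals[int(rng.integers(len(canonicals)))]
        species = f"{host.name}.iso{j + 1}"
        seq = _mutate(rng, host.sequence, off5, off3, mm)
        assert categorize(off5, off3, mm) == cat
        counts = [
            int(nb(base_mean)[0] + 1) if cond_of[s] == conditions[1] else 0 for s in samples
        ]
        rows[species] = counts
        meta[species] = {
            "kind": "exclusive-isomir",
            "category": cat,
            "canonical": host.name,
            "sequence": seq,
            "offsets": (off5, off3),
            "mismatches": mm,
        }
        exclusive_names.append(species)

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    truth = {
        "conditions": list(conditions),
        "condition_of": cond_of,
        "exclusive_to": {conditions[1]: exclusive_names},
        "flipped_precursors": flipped,
        "arm_flip_log2": arm_flip_log2,
        "species_meta": meta,
        "nb_size": nb_size,
        "base_mean": base_mean,
    }
    return counts, canonicals, truth


# --------------------------------------------------------------------------
# network / GSEA generator

def gen_network_data(
    n_genes: int = 400,
    n_up_mirnas: int = 9,
    n_down_mirnas: int = 14,
    targets_per_mirna: int = 3,
    decoys_per_mirna: int = 5,
    de_lfc: float = 1.5,
    gsea_set_size: int = 40,
    gsea_shift: float = -2.0,
    seed: int = 0,
):
    """Prediction and DE tables with planted anti-correlated edges.

    For each miRNA (``n_up_mirnas`` RISC-enriched, ``n_down_mirnas``
    de-enriched) ``targets_per_mirna`` target genes get a high/moderate
    CWCS and a significant mRNA change opposite to the miRNA direction;
    decoy predictions get excluded-tier CWCS or non-significant targets.
    Separately, ``gsea_set_size`` genes get their signature statistics
    shifted by ``gsea_shift`` (negative = planted downregulation) to form
    a ground-truth gene set for preranked GSEA.

    Returns (predictions, de_table, signature_stats, ground_truth) where
    predictions has columns (mirna, gene, cwcs), de_table columns
    (feature, log2fc, pvalue, padj), and signature_stats maps gene -> t.
    """
    rng = _rng(seed, "network")
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    mirnas = [f"miR-up-{i + 1}" for i in range(n_up_mirnas)] + [
        f"miR-down-{i + 1}" for i in range(n_down_mirnas)
    ]
    direction = {
        m: ("enriched" if m.startswith("miR-up") else "de-enriched") for m in mirnas
    }

    stats = {g: float(rng.normal(0.0, 1.0)) for g in genes}
    pred_rows = []
    planted_edges = []
    pool = rng.permutation(genes).tolist()
    for m in mirnas:
        for _ in range(targets_per_mirna):
            g = pool.pop()
            tier_high = rng.random() < 0.5
            cwcs = float(rng.uniform(-0.9, -0.41)) if tier_high else float(rng.uniform(-0.39, -0.21))
            pred_rows.append({"mirna": m, "gene": g, "cwcs": cwcs})
            # target regulated opposite to the miRNA's RISC change
            lfc = -de_lfc if direction[m] == "enriched" else de_lfc
            stats[g] = lfc * 2.5
            planted_edges.append(
                {"mirna": m, "gene": g, "tier": "high" if tier_high else "moderate",
                 "direction": direction[m], "log2fc": lfc}
            )
        for _ in range(decoys_per_mirna):
            g = pool.pop()
            if rng.random() < 0.5:
                cwcs = float(rng.uniform(-0.19, -0.01))  # excluded tier
            else:
                cwcs = float(rng.uniform(-0.9, -0.21))  # good tier, null target
            pred_rows.append({"mirna": m, "gene": g, "cwcs": cwcs})

    gsea_genes = sorted(rng.choice(
        [g for g in genes if g not in {e["gene"] for e in planted_edges}],
        size=gsea_set_size, replace=False,
    ).tolist())
    for g in gsea_genes:
        stats[g] = float(stats[g] + gsea_shift)

    planted_targets = {e["gene"]: e["log2fc"] for e in planted_edges}
    de_rows = []
    for g in genes:
        if g in planted_targets:
            lfc = planted_targets[g] + float(rng.normal(0.0, 0.1))
            p = float(rng.uniform(1e-8, 1e-4))
        else:
            lfc = float(rng.normal(0.0, 0.3))
            p = float(rng.uniform(0.2, 1.0))
        de_rows.append({"feature": g, "log2fc": lfc, "pvalue": p})
    de = pd.DataFrame(de_rows)
    from agodyn.isomirs import bh_adjust

    de["padj"] = bh_adjust(de["pvalue"].to_numpy())

    predictions = pd.DataFrame(pred_rows)
    truth = {
        "mirna_direction": direction,
        "planted_edges": [
            {k: e[k] for k in ("mirna", "gene", "tier", "direction")} for e in planted_edges
        ],
        "gsea_set": gsea_genes,
        "gsea_shift": gsea_shift,
    }
    return predictions, de, stats, truth
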