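"""Synthetic inputs with serialized ground truth for every pipeline stage.

Each generator is a pure function of its arguments (seed included) and emits,
alongside the data, a :class:`GroundTruth` record sufficient to score the
consuming module without re-running the generator. Scenario-specific RNG
streams are derived from the master seed so adding a scenario never perturbs
another.

What the generators emulate (and what they do not) is documented in the
package's methods note: substitutions-only genome pairs keep ANI expectations
exact; the pan-genome occupancy process is exchangeable across genomes so the
expected gene-discovery curve has exactly the exponential-with-offset form
the curve models fit; protein families are identity-separated; 16S panels
plant a known signature structure with exactly one in-group-exclusive
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .anib import AniMatrix
from .genome_io import GenomeAssembly, Proteome, SequenceRecord
from .pangenome import OrthoCluster, PangenomeMatrix, compartmentalize
from .signature import SignatureProfile

_BASES = np.array(list("ACGT"))
_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# fixed per-scenario stream tags (see module docstring)
_STREAMS = {"ani": 101, "ani_matrix": 102, "pangenome": 103,
            "proteomes": 104, "ssu": 105}


@dataclass
class GroundTruth:
    """Scenario tag plus whatever the scenario's tests need to score it."""

    scenario: str
    seed: int
    data: dict[str, Any] = field(default_factory=dict)


def _rng(scenario: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_STREAMS[scenario], seed]))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_bases(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    arr = np.array(list(seq))
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_genome_pair(length: int, substitution_rate: float, seed: int,
                         ) -> tuple[GenomeAssembly, GenomeAssembly, GroundTruth]:
    """An ancestor genome and a copy mutated by i.i.d. substitutions.

    Substitutions always change the base, so the realized mismatch count is
    Binomial(length, rate) exactly; the truth records it per 1,020-base
    fragment for direct comparison with per-fragment hits.
    """
    if not (0 <= substitution_rate <= 1):
        raise ValueError("substitution_rate must be in [0, 1]")
    if substitution_rate > 0.5:
        import warnings
        warnings.warn("substitution rates above 0.5 will start to lose fragments "
                      "to the 30/70 ANIb filters")
    rng = _rng("ani", seed)
    ancestor = _random_dna(rng, length)
    mutated_sites = np.nonzero(rng.random(length) < substitution_rate)[0]
    derived = _mutate_bases(rng, ancestor, mutated_sites)
    a = GenomeAssembly("sim_ancestor", [SequenceRecord("chr", ancestor)])
    b = GenomeAssembly("sim_derived", [SequenceRecord("chr", derived)])
    per_fragment = {}
    for start in range(0, length - 1019, 1020):
        in_frag = ((mutated_sites >= start) & (mutated_sites < start + 1020)).sum()
        per_fragment[f"chr:{start}-{start + 1020}"] = int(in_frag)
    truth = GroundTruth("ani", seed, {
        "substitution_rate": substitution_rate,
        "n_substitutions": int(len(mutated_sites)),
        "length": length,
        "per_fragment_mismatches": per_fragment,
    })
    return a, b, truth


def simulate_ani_matrix(cluster_sizes: list[int], seed: int,
                        within_range: tuple[float, float] = (96.0, 99.5),
                        between_range: tuple[float, float] = (74.0, 92.5),
                        ) -> tuple[AniMatrix, GroundTruth]:
    """A symmetric ANI matrix with planted genomospecies clusters.

    Within-cluster values are drawn above the 95% species threshold,
    between-cluster values below it; the planted partition is the ground
    truth for genomospecies clustering.
    """
    if within_range[0] < 95.0:
        raise ValueError("within-cluster ANI range must sit above the 95% threshold")
    if between_range[1] >= 95.0:
        raise ValueError("between-cluster ANI range must sit below the 95% threshold")
    rng = _rng("ani_matrix", seed)
    labels = []
    ids = []
    for c, size in enumerate(cluster_sizes):
        for k in range(size):
            ids.append(f"g{c:02d}_{k:02d}")
            labels.append(c)
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = within_range if labels[i] == labels[j] else between_range
            v = rng.uniform(lo, hi)
            values[i, j] = values[j, i] = v
    truth = GroundTruth("ani_matrix", seed, {
        "labels": dict(zip(ids, labels)),
        "n_clusters": len(cluster_sizes),
    })
    return AniMatrix(ids, values), truth


def simulate_pangenome(n_genomes: int, core_size: int, kappa: float, tau: float,
                       theta: float, seed: int
                       ) -> tuple[PangenomeMatrix, GroundTruth]:
    """Occupancy matrix whose expected discovery curve is exponential.

    Construction (exchangeable across genomes, so it holds for any genome
    ordering): ``core_size`` clusters present in every genome; ``theta``
    strain-specific clusters per genome (never shared); and M = kappa/q shell
    clusters, each present in each genome independently with probability
    q = 1 - exp(-1/tau). The expected new-gene curve is then exactly
    kappa * exp(-(g-1)/tau) + theta, and core(G) = core_size by construction
    (shell clusters are never allowed to reach full occupancy).
    """
    if n_genomes < 5:
        raise ValueError("need at least 5 genomes")
    rng = _rng("pangenome", seed)
    genomes = [f"genome_{k:03d}" for k in range(n_genomes)]
    clusters: list[OrthoCluster] = []

    def make_cluster(tag: str, idx: int, members: list[str]) -> OrthoCluster:
        return OrthoCluster(f"{tag}_{idx:05d}",
                            tuple((g, f"{tag}_{idx:05d}_{g}") for g in members),
                            "consensus")

    for i in range(core_size):
        clusters.append(make_cluster("SIMCORE", i, genomes))
    n_private = int(round(theta))
    k = 0
    for g in genomes:
        for _ in range(n_private):
            clusters.append(make_cluster("SIMPRIV", k, [g]))
            k += 1
    if kappa > 0:
        q = 1.0 - np.exp(-1.0 / tau)
        n_shell = int(round(kappa / q))
        membership = rng.random((n_shell, n_genomes)) < q
        for row in membership:
            present = np.nonzero(row)[0]
            if len(present) == 0:
                continue
            if len(present) == n_genomes:  # keep the core size exact
                present = present[:-1]
            clusters.append(make_cluster("SIMSHELL", len(clusters),
                                         [genomes[j] for j in present]))
    matrix = compartmentalize(clusters, genomes)
    truth = GroundTruth("pangenome", seed, {
        "omega_true": core_size, "kappa_true": kappa, "tau_true": tau,
        "theta_true": theta, "n_genomes": n_genomes,
    })
    return matrix, truth


@dataclass(frozen=True)
class FamilySpec:
    """One planted protein family: which genomes carry it and at how many
    copies, and the target pairwise identity between members."""

    name: str
    genomes: tuple[str, ...]
    copies: int = 1
    within_identity: float = 0.90
    length: int = 180


def simulate_proteomes(genomes: list[str], families: list[FamilySpec], seed: int,
                       min_separation: float = 0.2
                       ) -> tuple[list[Proteome], GroundTruth]:
    """Proteomes realizing the given family design.

    Each family member is the family ancestor mutated at per-site rate
    (1 - within_identity)/2, so expected pairwise identity between members is
    ~within_identity. Between-family identity is that of independent random
    proteins (a few percent). Errors if any family's within-identity is not
    separated from the 70/70 clustering floor by ``min_separation`` above
    random background — clustering tests would be ill-posed.
    """
    for fam in families:
        if fam.within_identity < 0.40 + min_separation:
            raise ValueError(
                f"family {fam.name}: within-identity {fam.within_identity} too close "
                "to random background; separation gap violated")
    rng = _rng("proteomes", seed)
    proteins: dict[str, list[SequenceRecord]] = {g: [] for g in genomes}
    truth_members: dict[str, list[tuple[str, str]]] = {}
    for fam in families:
        unknown = set(fam.genomes) - set(genomes)
        if unknown:
            raise ValueError(f"family {fam.name} names unknown genomes {sorted(unknown)}")
        ancestor = "".join(rng.choice(_AMINO, size=fam.length))
        rate = (1.0 - fam.within_identity) / 2.0
        members = []
        for g in fam.genomes:
            for c in range(fam.copies):
                arr = np.array(list(ancestor))
                sites = np.nonzero(rng.random(fam.length) < rate)[0]
                for p in sites:
                    choices = [a for a in _AMINO if a != arr[p]]
                    arr[p] = choices[rng.integers(0, len(choices))]
                pid = f"{fam.name}_{g}_c{c}"
                proteins[g].append(SequenceRecord(pid, "".join(arr), kind="protein"))
                members.append((g, pid))
        truth_members[fam.name] = members
    proteomes = [Proteome(g, proteins[g]) for g in genomes if proteins[g]]
    truth = GroundTruth("proteomes", seed, {
        "families": truth_members,
        "genomes": list(genomes),
    })
    return proteomes, truth


def separated_family_design(n_families: int, genomes: list[str],
                            within_identity: float = 0.90, copies: int = 1,
                            length: int = 180) -> list[FamilySpec]:
    """Single-copy families present in every genome (clustering oracle set)."""
    return [FamilySpec(f"fam{k:03d}", tuple(genomes), copies, within_identity, length)
            for k in range(n_families)]


def pan_gene_design(ingroup: list[str], outgroup: list[str],
                    n_exclusive: int = 24, n_shared: int = 8,
                    within_identity: float = 0.92, length: int = 150
                    ) -> list[FamilySpec]:
    """Families mirroring a pan-gene screen: ``n_exclusive`` families in every
    in-group genome only, plus ``n_shared`` families in all genomes."""
    everyone = tuple(ingroup) + tuple(outgroup)
    specs = [FamilySpec(f"excl{k:03d}", tuple(ingroup), 1, within_identity, length)
             for k in range(n_exclusive)]
    specs += [FamilySpec(f"shared{k:03d}", everyone, 1, within_identity, length)
              for k in range(n_shared)]
    return specs


def simulate_16s_panel(n_ingroup: int = 10, n_outgroup: int = 8,
                       n_positions: int = 37, seed: int = 0,
                       reference_length: int = 1540,
                       region: tuple[int, int] = (50, 650),
                       outgroup_divergence: float = 0.03,
                       ) -> tuple[list[SequenceRecord], list[SequenceRecord],
                                  SequenceRecord, SignatureProfile, GroundTruth]:
    """16S panel with planted signature structure.

    Returns (ingroup, outgroup, reference, profile, truth). In-group
    sequences carry the expected base at every signature position and at most
    two substitutions elsewhere in the screening region (identity stays above
    the 99.6% threshold). Out-group sequences diverge at ~``outgroup_divergence``
    in the region, each misses at least one signature state, exactly one
    designated position (the planted analogue of a species-exclusive site) is
    missed by every out-group sequence, and every other position is carried
    by at least one out-group sequence — so exactly one position is
    exclusive, while the full combination is carried by no out-group record.
    """
    lo, hi = region
    if n_positions > (hi - lo) // 2:
        raise ValueError("too many signature positions for the region")
    rng = _rng("ssu", seed)
    ref_seq = _random_dna(rng, reference_length)
    sig_positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_positions,
                                       replace=False))
    profile = SignatureProfile(
        "sim_reference",
        tuple((int(p), ref_seq[p - 1]) for p in sig_positions),
    )
    reference = SequenceRecord("sim_reference", ref_seq)
    sig_set = set(int(p) for p in sig_positions)
    region_nonsig = [p for p in range(lo, hi + 1) if p not in sig_set]

    ingroup = []
    for k in range(n_ingroup):
        n_mut = int(rng.integers(0, 3))  # 0-2 substitutions keep identity >= 99.6%
        sites = rng.choice(region_nonsig, size=n_mut, replace=False) - 1
        seq = _mutate_bases(rng, ref_seq, np.asarray(sites, dtype=int))
        ingroup.append(SequenceRecord(f"in_{k:02d}", seq))

    exclusive_pos = int(rng.choice(sig_positions))
    outgroup = []
    carried = {int(p): False for p in sig_positions if int(p) != exclusive_pos}
    for k in range(n_outgroup):
        sites = [p - 1 for p in region_nonsig
                 if rng.random() < outgroup_divergence]
        seq = _mutate_bases(rng, ref_seq, np.asarray(sites, dtype=int))
        flip = [exclusive_pos - 1]
        for p in sig_positions:
            p = int(p)
            if p != exclusive_pos and rng.random() < 0.3:
                flip.append(p - 1)
        seq = _mutate_bases(rng, seq, np.asarray(flip, dtype=int))
        flipped = {f + 1 for f in flip}
        for p in carried:
            if p not in flipped:
                carried[p] = True
        outgroup.append(SequenceRecord(f"out_{k:02d}", seq))
    # guarantee every non-exclusive position is carried by someone out-group
    for p, ok in carried.items():
        if not ok:
            k = int(rng.integers(0, n_outgroup))
            seq = list(outgroup[k].sequence)
            seq[p - 1] = ref_seq[p - 1]
            outgroup[k] = SequenceRecord(outgroup[k].id, "".join(seq))
    truth = GroundTruth("ssu", seed, {
        "exclusive_position": exclusive_pos,
        "signature_positions": [int(p) for p in sig_positions],
        "ingroup_ids": [s.id for s in ingroup],
        "outgroup_ids": [s.id for s in outgroup],
    })
    return ingroup, outgroup, reference, profile, truth
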