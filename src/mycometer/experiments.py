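"""End-to-end validation experiments.

Each function runs one benchmark of the toolkit on data from
:mod:`mycometer.simkit` under the study conditions the package targets
(588/142 bp flanks, 550 bp ITS, 400-800 bp pairing window, 50 bp end trim,
MAPQ 30, depth-15 filter, copy numbers spanning 7-170) and returns plain
dictionaries of summary numbers.  They back both the acceptance checks in
the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import depthcn, mockbench, rdna_hmm, simkit

UNIT = 588 + 550 + 142
SPACER = 2000


def _flank_profiles(seed: int):
    rng = np.random.default_rng(seed)
    lsu_t = simkit.random_seq(rng, 588)
    ssu_t = simkit.random_seq(rng, 142)
    lsu = rdna_hmm.build_profile(
        simkit.flank_training_alignment(lsu_t, 10, 0.02, seed=seed + 1), "LSU")
    ssu = rdna_hmm.build_profile(
        simkit.flank_training_alignment(ssu_t, 10, 0.02, seed=seed + 2), "SSU")
    lsu.calibrate(reference=lsu_t, seed=seed + 3)
    ssu.calibrate(reference=ssu_t, seed=seed + 4)
    return (lsu_t, ssu_t), (lsu, ssu)


def _array_genome(K, templates, divergence, seed, truncate=False,
                  markers=(5, 800)):
    spec = simkit.SyntheticGenomeSpec(
        contig_lengths=(K * (UNIT + SPACER) + 12_000,),
        arrays=(simkit.ArraySpec(0, 8000, K, SPACER),),
        flank_templates=templates, flank_divergence=divergence,
        truncate_last_copy=truncate, marker_genes=markers, seed=seed)
    return simkit.synthesize_genome(spec, name=f"g{seed}")


def cn_hmm_recovery(n_genomes: int = 100, k_values=(1, 2, 5, 20, 60, 150),
                    max_divergence: float = 0.05, seed: int = 0) -> dict:
    """Exact copy-number recovery on seeded genomes with flank divergence
    drawn uniformly up to ``max_divergence``."""
    templates, (lsu, ssu) = _flank_profiles(seed)
    rng = np.random.default_rng(seed + 10)
    exact = 0
    per_k: dict[int, list[bool]] = {k: [] for k in k_values}
    for g in range(n_genomes):
        K = k_values[g % len(k_values)]
        div = float(rng.uniform(0.0, max_divergence))
        asm, _ = _array_genome(K, templates, div, int(rng.integers(0, 2**31 - 1)))
        res = rdna_hmm.cn_hmm_pipeline(asm, lsu, ssu, genome=asm.name)
        hit = res.copy_number == K
        exact += hit
        per_k[K].append(hit)
    return {"n": n_genomes, "exact": exact,
            "recovery_percent": 100.0 * exact / n_genomes,
            "per_k": {k: sum(v) for k, v in per_k.items()}}


def truncation_recovery(n_genomes: int = 12, k_values=(2, 3, 5, 8),
                        seed: int = 0) -> dict:
    """Contig-end rule: the copy whose SSU flank runs off the contig end is
    still counted, so genomes built truncated recover exactly K."""
    templates, (lsu, ssu) = _flank_profiles(seed)
    rng = np.random.default_rng(seed + 20)
    exact = 0
    truncated_flagged = 0
    for g in range(n_genomes):
        K = k_values[g % len(k_values)]
        asm, _ = _array_genome(K, templates, float(rng.uniform(0, 0.03)),
                               int(rng.integers(0, 2**31 - 1)), truncate=True)
        res = rdna_hmm.cn_hmm_pipeline(asm, lsu, ssu, genome=asm.name)
        exact += res.copy_number == K
        truncated_flagged += sum(
            l.completeness == "end_truncated" for l in res.loci) == 1
    return {"n": n_genomes, "exact": exact,
            "recovery_percent": 100.0 * exact / n_genomes,
            "single_truncated_flag_percent": 100.0 * truncated_flagged / n_genomes}


def cn_md_recovery(k_values=(7, 60, 170), n_per_k: int = 10,
                   coverage: float = 30.0, read_length: int = 100,
                   error_rate: float = 0.005, seed: int = 0) -> dict:
    """Mapping-depth copy-number recovery across the observed 7-170 range at
    ~30x marker coverage; returns the truth-vs-estimate regression slope."""
    rng = np.random.default_rng(seed)
    truths, estimates = [], []
    rel_err_by_k: dict[int, list[float]] = {k: [] for k in k_values}
    for K in k_values:
        for _ in range(n_per_k):
            gseed = int(rng.integers(0, 2**31 - 1))
            spec = simkit.SyntheticGenomeSpec(
                contig_lengths=(K * (UNIT + SPACER) + 20_000,),
                arrays=(simkit.ArraySpec(0, 8000, K, SPACER),),
                flank_divergence=0.02, marker_genes=(8, 1000), seed=gseed)
            asm, truth = simkit.synthesize_genome(spec, name=f"g{gseed}")
            n_reads = int(coverage * asm.total_length / read_length)
            reads = simkit.simulate_shotgun_reads(
                asm, simkit.ReadSimParams(n_reads, read_length, error_rate,
                                          int(rng.integers(0, 2**31 - 1))))
            markers = {m[3]: asm.contigs[m[0]][m[1]:m[2]]
                       for m in truth.marker_loci}
            res = depthcn.cn_md_pipeline(reads, {"ITS": truth.its_sequence},
                                         markers, sample=asm.name)
            truths.append(K)
            estimates.append(res.cn_md)
            rel_err_by_k[K].append((res.cn_md - K) / K)
    slope = float(np.polyfit(truths, estimates, 1)[0])
    mean_rel_err = float(np.mean([(e - t) / t for e, t in zip(estimates, truths)]))
    return {"n": len(truths), "slope": slope,
            "mean_relative_error": mean_rel_err,
            "max_abs_rel_error_by_k": {k: float(np.max(np.abs(v)))
                                       for k, v in rel_err_by_k.items()},
            "truths": truths, "estimates": estimates}


def method_comparison(n_replicates: int = 10, n_communities: int = 5,
                      n_reads: int = 50_000, seed: int = 0) -> dict:
    """ITS-vs-shotgun mock-community benchmark: weighted UniFrac to the known
    composition per method, at species and genus rank, over seeded
    replicates of ``n_communities`` mock communities each."""
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        reps.append(mockbench.compare_methods(
            n_communities=n_communities, n_reads=n_reads,
            seed=int(rng.integers(0, 2**31 - 1))))
    its_worse = sum(r["species"]["its"] > r["species"]["shotgun"] for r in reps)
    gaps_sp = [r["species"]["its"] - r["species"]["shotgun"] for r in reps]
    gaps_gen = [r["genus"]["its"] - r["genus"]["shotgun"] for r in reps]
    mean = lambda key, lvl: float(np.mean([r[lvl][key] for r in reps]))
    return {
        "n_replicates": n_replicates,
        "unifrac_species_its": mean("its", "species"),
        "unifrac_species_shotgun": mean("shotgun", "species"),
        "unifrac_genus_its": mean("its", "genus"),
        "unifrac_genus_shotgun": mean("shotgun", "genus"),
        "its_worse_at_species": its_worse,
        "species_gap": float(np.mean(gaps_sp)),
        "genus_gap": float(np.mean(gaps_gen)),
    }


def sparcc_calibration(n_taxa: int = 50, n_samples: int = 200,
                       planted_rho: float = 0.8, n_sign_reps: int = 20,
                       depth: int = 20_000, seed: int = 0) -> dict:
    """Type-I control on an independent basis plus sign recovery of a planted
    basis correlation."""
    from . import ecologynet

    sim = simkit.simulate_compositional_counts(n_samples, n_taxa, depth=depth,
                                               seed=seed)
    rho = ecologynet.sparcc(sim.counts).to_numpy()
    off = np.abs(rho[np.triu_indices(n_taxa, 1)])
    rng = np.random.default_rng(seed + 1)
    correct_sign = 0
    for _ in range(n_sign_reps):
        s = simkit.simulate_compositional_counts(
            n_samples, n_taxa, [(0, 1, planted_rho)], depth=depth,
            seed=int(rng.integers(0, 2**31 - 1)))
        r = ecologynet.sparcc(s.counts)
        correct_sign += (r.iloc[0, 1] > 0) == (planted_rho > 0)
    return {"n_pairs": off.size,
            "percent_above_0.3": 100.0 * float((off > 0.3).mean()),
            "median_abs_rho": float(np.median(off)),
            "n_sign_reps": n_sign_reps,
            "sign_recovery_percent": 100.0 * correct_sign / n_sign_reps}


def powerlaw_recovery(n: int = 2000, alpha: float = 2.5, seed: int = 0) -> dict:
    """Discrete MLE recovery of a known power-law exponent."""
    from . import ecologynet

    deg = ecologynet.sample_powerlaw(n, alpha, seed=seed)
    fit = ecologynet.powerlaw_fit(deg)
    return {"n": n, "alpha_true": alpha, "alpha_hat": fit.alpha,
            "ks_stat": fit.ks_stat}
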