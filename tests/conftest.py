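import numpy as np
import pytest

from mycometer import rdna_hmm, simkit

LSU_LEN, SSU_LEN = 588, 142
ITS_LEN = 550
UNIT = LSU_LEN + ITS_LEN + SSU_LEN  # one rDNA repeat without the spacer
SPACER = 2000


@pytest.fixture(scope="session")
def flank_templates():
    """One shared LSU/SSU flank template pair: the flanks are conserved
    across fungi, so every synthetic genome plants diverged copies of the
    same pair and a single profile pair scans them all."""
    rng = np.random.default_rng(20240917)
    return simkit.random_seq(rng, LSU_LEN), simkit.random_seq(rng, SSU_LEN)


@pytest.fixture(scope="session")
def profiles(flank_templates):
    """Calibrated LSU and SSU profile HMMs trained on 10-sequence, 2%%
    divergence alignments of the templates."""
    lsu_t, ssu_t = flank_templates
    lsu = rdna_hmm.build_profile(
        simkit.flank_training_alignment(lsu_t, 10, 0.02, seed=1), name="LSU")
    ssu = rdna_hmm.build_profile(
        simkit.flank_training_alignment(ssu_t, 10, 0.02, seed=2), name="SSU")
    lsu.calibrate(reference=lsu_t, seed=3)
    ssu.calibrate(reference=ssu_t, seed=4)
    return lsu, ssu


@pytest.fixture(scope="session")
def make_genome(flank_templates):
    """Factory for assemblies with K planted tandem ITS copies."""

    def build(K, divergence=0.0, seed=0, truncate=False, markers=(5, 800),
              spacer=SPACER):
        contig = K * (UNIT + spacer) + 12_000
        spec = simkit.SyntheticGenomeSpec(
            contig_lengths=(contig,),
            arrays=(simkit.ArraySpec(contig=0, start=8000, copy_number=K,
                                     spacer_length=spacer),),
            flank_templates=flank_templates,
            flank_divergence=divergence,
            truncate_last_copy=truncate,
            marker_genes=markers,
            seed=seed,
        )
        return simkit.synthesize_genome(spec, name=f"g{seed}")

    return build
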