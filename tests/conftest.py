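import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles module

from plantmir.io import write_fasta
from plantmir.synthetic import (
    generate_genome, generate_mature_reference, generate_target_transcriptome,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One 80-kb chromosome with 6 planted precursors (1 intragenic, one
    2-member antiparallel cluster), written to disk with mature reference
    and target transcriptome."""
    outdir = tmp_path_factory.mktemp("smallsim")
    sim = generate_genome(
        n_chroms=1, chrom_len=80_000, n_precursors=6,
        frac_intragenic=0.2, frac_clustered=0.3, seed=11,
    )
    paths = sim.write(outdir)
    matures = generate_mature_reference(sim.truth, n_decoys=10, seed=11)
    matures_path = outdir / "matures.fa"
    write_fasta(matures, matures_path)
    transcripts = generate_target_transcriptome(sim.truth, seed=11)
    tx_path = outdir / "transcripts.fa"
    write_fasta(transcripts, tx_path)
    return {
        "sim": sim,
        "truth": sim.truth,
        "paths": paths,
        "matures": matures,
        "matures_path": matures_path,
        "transcripts": transcripts,
        "transcripts_path": tx_path,
        "outdir": outdir,
    }
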