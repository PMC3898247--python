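import numpy as np
import pytest

import mtscope as m


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The reference synthetic dataset (error-free), simulated once."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = m.default_config(seed=1, error_rate=0.0)
    res = m.simulate_dataset(cfg, outdir)
    res["config"] = cfg
    return res


@pytest.fixture(scope="session")
def default_tracks(default_sim):
    """Coverage track and pileup computed from the reference dataset."""
    genome = default_sim["genome"]
    track = m.compute_doc(default_sim["sam"], genome)
    pileup = m.build_pileup(default_sim["sam"], genome)
    return {"track": track, "pileup": pileup}


def make_genome(seq: str, gid: str = "g") -> m.CircularGenome:
    return m.CircularGenome(id=gid, sequence=seq)


def write_sam(path, genome, reads):
    """Minimal SAM writer for hand-built reads.

    ``reads`` is a list of (name, flag, pos0, cigar, seq) tuples.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{genome.id}\tLN:{genome.length}\n")
        for name, flag, pos, cigar, seq in reads:
            fh.write(
                f"{name}\t{flag}\t{genome.id}\t{pos + 1}\t60\t{cigar}\t*\t0\t0"
                f"\t{seq}\t{'I' * len(seq)}\n"
            )
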