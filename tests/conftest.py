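import numpy as np
import pytest

from mirscreen import essentiality as ess
from mirscreen import simulate as sim


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_annotations():
    """Handcrafted 3-hairpin GFF3 + FASTA: plus-strand two-arm, minus-strand
    two-arm, and single-arm hairpins, plus one orphan FASTA entry."""
    rng = np.random.default_rng(0)
    seqs = {"MIH1": _random_seq(80, rng), "MIH2": _random_seq(60, rng),
            "MIH3": _random_seq(60, rng)}
    gff = "\n".join(
        [
            "##gff-version 3",
            "chr1\t.\tmiRNA_primary_transcript\t101\t180\t.\t+\t.\tID=MIH1;Name=hp-plus",
            "chr1\t.\tmiRNA\t101\t122\t.\t+\t.\tID=MIH1a;Name=hp-plus-5p;Derives_from=MIH1",
            "chr1\t.\tmiRNA\t151\t172\t.\t+\t.\tID=MIH1b;Name=hp-plus-3p;Derives_from=MIH1",
            "chr1\t.\tmiRNA_primary_transcript\t301\t360\t.\t-\t.\tID=MIH2;Name=hp-minus",
            "chr1\t.\tmiRNA\t339\t360\t.\t-\t.\tID=MIH2a;Name=hp-minus-5p;Derives_from=MIH2",
            "chr1\t.\tmiRNA\t301\t322\t.\t-\t.\tID=MIH2b;Name=hp-minus-3p;Derives_from=MIH2",
            "chr1\t.\tmiRNA_primary_transcript\t501\t560\t.\t+\t.\tID=MIH3;Name=hp-single",
            "chr1\t.\tmiRNA\t501\t522\t.\t+\t.\tID=MIH3a;Name=hp-single-5p;Derives_from=MIH3",
        ]
    )
    fasta = "".join(f">{k}\n{v}\n" for k, v in seqs.items()) + f">ORPHAN\n{_random_seq(30, rng)}\n"
    return gff, fasta


@pytest.fixture(scope="session")
def mirnome_fixture():
    return sim.simulate_mirnome_fixture(
        n_hairpins=3, genome_length=3000, n_planted_offtargets=2, seed=11
    )


@pytest.fixture(scope="session")
def reference_sets():
    return ess.ReferenceSets(
        essential=frozenset(f"ESS{j + 1:03d}" for j in range(100)),
        nonessential=frozenset(f"NON{j + 1:03d}" for j in range(100)),
    )


@pytest.fixture(scope="session")
def planted_screen(reference_sets):
    """Small planted dropout screen shared by essentiality tests."""
    manifest = sim.synthetic_manifest(n_hairpins=100, n_three_guide=4, seed=21)
    params = sim.ScreenSimParams(seed=22)
    truth = sim.plant_essentials(manifest, 10, params)
    counts = sim.simulate_screen_counts(manifest, truth, params)
    return manifest, truth, counts
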