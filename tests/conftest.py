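import numpy as np
import pytest

from triorecess.model import (
    Consequence,
    GenotypeState,
    TrioGenotypes,
    VariantRecord,
    make_trio,
)


@pytest.fixture(scope="session")
def gnat1_transcript():
    from triorecess.io import load_gnat1_transcript

    return load_gnat1_transcript()


@pytest.fixture(scope="session")
def gnat1_domains():
    from triorecess.io import load_gnat1_domains

    return load_gnat1_domains()


def variant(
    chrom="1",
    pos=100,
    ref="A",
    alt="T",
    consequence=Consequence.missense,
    pop_freqs=None,
    gene="GENE1",
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        consequence=consequence,
        pop_freqs=pop_freqs or {},
        gene=gene,
    )


def trio(
    proband=GenotypeState.hom_alt,
    mother=GenotypeState.het,
    father=GenotypeState.het,
    **variant_kwargs,
) -> TrioGenotypes:
    return make_trio(variant(**variant_kwargs), proband, mother, father)


def random_trio_table(rng: np.random.Generator, n: int) -> list[TrioGenotypes]:
    """A random variant table exercising every branch of the cascade."""
    states = [
        GenotypeState.hom_ref,
        GenotypeState.het,
        GenotypeState.hom_alt,
        GenotypeState.missing,
    ]
    consequences = list(Consequence)
    out = []
    for i in range(n):
        freqs = {}
        for db in ("AF_EXAC", "AF_1KG", "AF_EVS"):
            if rng.random() < 0.6:
                freqs[db] = float(rng.choice([0.0, 0.001, 0.005, 0.0051, 0.02, 0.3]))
        out.append(
            make_trio(
                variant(
                    chrom=str(rng.integers(1, 5)),
                    pos=i + 1,
                    consequence=consequences[rng.integers(len(consequences))],
                    pop_freqs=freqs,
                    gene=f"G{rng.integers(1, max(2, n // 4))}",
                ),
                *(states[rng.integers(4)] for _ in range(3)),
            )
        )
    return out
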