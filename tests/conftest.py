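import numpy as np
import pytest

import streakscan as sk


@pytest.fixture(scope="session")
def cabl_pattern():
    """The A/C-rich consensus parsed from its slash-degenerate form."""
    return sk.parse_consensus("AA/CAACAAA/C")


@pytest.fixture(scope="session")
def cabl_pfm_model(cabl_pattern):
    """PFM built from the consensus: 10 counts for allowed bases, 1 otherwise."""
    return sk.MotifModel(id="cabl_like", pfm=sk.consensus_to_pfm(cabl_pattern))


@pytest.fixture(scope="session")
def table2_counts():
    """Printed case-control genotype tallies (controls, dry-arm cases)."""
    return {
        "controls": sk.GenotypeCounts(hom_ref=89, het=39, hom_alt=8, group_label="controls"),
        "cases": sk.GenotypeCounts(hom_ref=63, het=138, hom_alt=58, group_label="cases"),
    }


@pytest.fixture
def streak_for_calling():
    """A VariantStreak whose span is the full composite allele string; the
    trailing non-variant C anchors the alignment inside repeat sequence."""
    variants = [
        sk.Variant(id=f"s{i}", chrom="chr10", pos=off + 1, ref="C", alt="A", maf=0.273)
        for i, off in enumerate(sk.STREAK_SNP_OFFSETS)
    ]
    return sk.VariantStreak(
        variants=tuple(variants),
        span=sk.GenomicRegion(chrom="chr10", start=1, end=len(sk.WT_STREAK)),
        wt_allele=sk.WT_STREAK,
        mt_allele=sk.MT_STREAK,
    )


def random_pfm(width: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(1, 30, size=(width, 4)).astype(float)
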