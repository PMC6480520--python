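import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from distfrac.simulator import SimulationConfig

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

SAMPLES = [f"S{i}" for i in range(1, 17)]
POP_OF = {s: p for s, p in zip(
    SAMPLES, ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["O"] * 4)}


def vcf_text(records):
    header = (
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=1,length=100000>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(SAMPLES) + "\n")
    return header + "".join(records)


def vcf_record(pos, ref, alt, gts):
    return (f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts) + "\n")


def pattern_record(pos, pattern):
    """Fixed four-taxon pattern, e.g. 'ABBA' -> per-pop diploid genotypes."""
    gts = []
    for allele in pattern:
        gt = "1|1" if allele == "B" else "0|0"
        gts.extend([gt] * 4)
    return vcf_record(pos, "A", "T", gts)


@pytest.fixture
def popmap_file(tmp_path):
    path = tmp_path / "popmap.tsv"
    path.write_text("".join(f"{s}\t{p}\n" for s, p in POP_OF.items()))
    return path


@pytest.fixture
def popmap():
    return dict(POP_OF)


@pytest.fixture
def toy_vcf(tmp_path):
    """Three fixed sites: ABBA, BABA, BBAA (REF is the ancestral allele)."""
    path = tmp_path / "toy.vcf"
    path.write_text(vcf_text([
        pattern_record(101, "ABBA"),
        pattern_record(201, "BABA"),
        pattern_record(301, "BBAA"),
    ]))
    return path


@pytest.fixture
def ms_text():
    return (
        "ms 8 2 -I 4 2 2 2 2 -r 0 100\n"
        "1 2 3\n"
        "\n"
        "//\n"
        "segsites: 3\n"
        "positions: 0.10 0.50 0.90\n"
        "000\n"
        "010\n"
        "011\n"
        "011\n"
        "110\n"
        "111\n"
        "000\n"
        "000\n"
        "\n"
        "//\n"
        "segsites: 0\n")


@pytest.fixture
def fast_config():
    """Baseline demography on a smaller locus for quick Monte-Carlo tests."""
    return SimulationConfig(L=2000, rho=20.0)


def fixed_pattern_freqs(pattern):
    """'ABBA' -> (p1, p2, p3, p4) with B = derived."""
    return tuple(1.0 if a == "B" else 0.0 for a in pattern)


def all_fixed_patterns():
    """All 16 fixed four-taxon patterns as frequency tuples."""
    out = []
    for bits in range(16):
        out.append(tuple(float((bits >> i) & 1) for i in range(4)))
    return out


def naive_pattern_d(patterns):
    """Literal ABBA/BABA string counting over fixed-site windows."""
    n_abba = sum(1 for p in patterns if p == (0.0, 1.0, 1.0, 0.0))
    n_baba = sum(1 for p in patterns if p == (1.0, 0.0, 1.0, 0.0))
    if n_abba + n_baba == 0:
        return float("nan")
    return (n_abba - n_baba) / (n_abba + n_baba)
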