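import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """A 60-gene two-condition synthetic genome with its segmentations."""
    from apadiff.annotation import build_all_segmentations
    from apadiff.synthetic import generate_genome

    genome = generate_genome(60, seed=101)
    segmentations, exclusions = build_all_segmentations(
        genome.transcripts, genome.sites
    )
    assert not exclusions
    return genome, segmentations


@pytest.fixture(scope="session")
def small_samples(small_genome):
    from apadiff.synthetic import simulate_counts

    genome, _ = small_genome
    return simulate_counts(
        genome.truth, n_replicates=3, mean_depth=300.0, dispersion=0.1, seed=102
    )


def by_condition(samples, condition):
    return [s for s in samples if s.condition == condition]


def sam_text(chrom_lengths, records):
    """Minimal SAM: records are (qname, flag, chrom, pos0, length)."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    for qname, flag, chrom, pos0, length in records:
        lines.append(
            "\t".join(
                [qname, str(flag), chrom, str(pos0 + 1), "60", f"{length}M",
                 "*", "0", "0", "A" * length, "*"]
            )
        )
    return "\n".join(lines) + "\n"
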