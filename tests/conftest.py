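"""Shared fixtures: hand-built flatfiles and small synthetic studies."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mitorder.synthetic import SimConfig, simulate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def genbank_text(seq: str, features: str, name: str = "TEST00001",
                 topology: str = "circular") -> str:
    """Minimal GenBank flatfile with hand-controlled feature lines."""
    lines = [
        f"LOCUS       {name}             {len(seq)} bp    DNA     "
        f"{topology} INV 01-JAN-2024",
        "DEFINITION  synthetic test record.",
        f"ACCESSION   {name}",
        f"VERSION     {name}.1",
        "FEATURES             Location/Qualifiers",
        "     source          1.." + str(len(seq)),
        '                     /organism="synthetic construct"',
    ]
    lines.extend(features.rstrip("\n").split("\n"))
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def gb_record(tmp_path):
    """200 bp circular record with 3 hand-placed features (one wraps)."""
    seq = "ACGT" * 50
    feats = (
        "     CDS             10..45\n"
        '                     /gene="COX1"\n'
        "     tRNA            complement(50..110)\n"
        '                     /product="tRNA-Asp"\n'
        "     CDS             join(150..200,1..40)\n"
        '                     /gene="ND1"'
    )
    path = tmp_path / "rec.gb"
    path.write_text(genbank_text(seq, feats))
    return path


@pytest.fixture(scope="session")
def clean_study():
    """Zero-noise 4-tip synthetic study: the exact-recovery reference."""
    return simulate_study(SimConfig(seed=42, n_tips=4))


@pytest.fixture(scope="session")
def noisy_config():
    return SimConfig(
        seed=7, n_tips=3, drop_prob=0.15, jitter_bp=2,
        false_call_prob=0.3, structure_omission_prob=0.3,
    )
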