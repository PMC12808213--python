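"""Shared fixtures: one session-scoped synthetic dataset plus helpers.

``brute_force_junction_tally`` is an independent CIGAR walk (kept
deliberately separate from the package implementation) used as the
oracle for support-conservation checks.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import pyfaidx
import pytest

from spliceaudit import synthdata


@pytest.fixture(scope="session")
def sim_config() -> synthdata.SimConfig:
    return synthdata.SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory, sim_config) -> dict[str, Path]:
    outdir = tmp_path_factory.mktemp("sim")
    return synthdata.simulate(sim_config, outdir)


@pytest.fixture(scope="session")
def sim_fasta(sim_paths) -> pyfaidx.Fasta:
    return pyfaidx.Fasta(str(sim_paths["genome"]))


@pytest.fixture(scope="session")
def junction_truth(sim_paths) -> pd.DataFrame:
    return pd.read_csv(sim_paths["junction_truth"], sep="\t")


@pytest.fixture(scope="session")
def expression_tables(sim_config) -> dict:
    return synthdata.make_expression(sim_config)


def brute_force_junction_tally(sam_path, min_anchor: int = 8) -> dict:
    """Independent (read, junction) incidence tally over primary mapped
    records: segment the CIGAR at N ops and keep junctions whose
    neighbouring reference segments are long enough."""
    tally: dict[tuple[str, int, int], int] = {}
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        fields = line.rstrip("\n").split("\t")
        flag = int(fields[1])
        if flag & (0x4 | 0x100 | 0x800):
            continue
        chrom, pos, cigar = fields[2], int(fields[3]) - 1, fields[5]
        segments: list[int] = []  # reference lengths of aligned blocks
        gaps: list[tuple[int, int]] = []  # candidate junctions between blocks
        cursor, seg = pos, 0
        for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            length = int(length)
            if op == "N":
                segments.append(seg)
                gaps.append((cursor, cursor + length))
                cursor += length
                seg = 0
            elif op in "MD=X":
                cursor += length
                seg += length
        segments.append(seg)
        for i, (s, e) in enumerate(gaps):
            if segments[i] >= min_anchor and segments[i + 1] >= min_anchor:
                key = (chrom, s, e)
                tally[key] = tally.get(key, 0) + 1
    return tally


@pytest.fixture(scope="session")
def brute_tally():
    return brute_force_junction_tally
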