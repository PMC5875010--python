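import numpy as np
import pytest

from apakit import CoverageProfile, PolyASite, TerminalExon


@pytest.fixture
def exon_factory():
    """Build a terminal exon plus per-sample coverage profiles.

    ``values_by_sample`` maps sample id to a coverage array covering the
    exon plus a 200-nt 3' extension; ``site_offsets`` are transcript-
    oriented offsets of the cleavage bases.
    """

    def build(values_by_sample, site_offsets, strand="+", start=10_000,
              ext3=200, exon_id="exonA", chrom="chr1"):
        any_values = next(iter(values_by_sample.values()))
        length = len(any_values) - ext3
        exon = TerminalExon(chrom, start, start + length, strand, exon_id)
        for j, off in enumerate(site_offsets):
            pos = start + off if strand == "+" else start + length - 1 - off
            exon.sites.append(PolyASite(chrom, pos, strand, f"{exon_id}_s{j}",
                                        exon_id=exon_id))
        profiles = {
            sample: CoverageProfile(exon_id, sample, np.asarray(vals, float),
                                    strand, 0, ext3, exon)
            for sample, vals in values_by_sample.items()
        }
        return exon, profiles

    return build


@pytest.fixture
def write_fasta(tmp_path):
    def write(records, name="genome.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return str(path)

    return write
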