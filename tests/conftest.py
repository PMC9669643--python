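import pytest

from plastopipe.model import AnnotationSet, CircularSequence, SequenceRecord
from plastopipe.formats import write_fasta, write_genbank
from plastopipe.synthetic import generate_plastome

# toy 24-bp plastome: LSC [0,8) IRb [8,14) SSC [14,18) IRa [18,24)
T1 = "ACTCACTCAACCGGCTCCCCGGTT"

#: detector parameters scaled for kilobase-sized test genomes
DETECT_KW = {"min_length": 100, "min_identity": 0.95}


@pytest.fixture(scope="session")
def truth():
    return generate_plastome(2000, 400, 600, rng_seed=42)


@pytest.fixture()
def toy():
    return CircularSequence("T1", T1)


@pytest.fixture(scope="session")
def truth_annotation(truth):
    return AnnotationSet(
        sequence=truth.annotation.sequence,
        features=truth.annotation.features,
        organism=truth.annotation.organism,
    )


@pytest.fixture()
def ref_gb_path(tmp_path, truth_annotation):
    path = tmp_path / "reference.gb"
    write_genbank(truth_annotation, str(path))
    return str(path)


def write_sample_inputs(tmp_path, truth, name, bases):
    """Write an assembly FASTA for a (possibly transformed) genome."""
    path = tmp_path / f"{name}.fasta"
    write_fasta([SequenceRecord(name, "", bases)], str(path))
    return str(path)
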