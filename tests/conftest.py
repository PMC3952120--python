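import pytest

from fourbody import load_reference_potential
from fourbody.evaluation import load_benchmark_table


def make_atom_line(serial, name, resname, chain, resseq, x, y, z,
                   occupancy=1.0, element=None, altloc=" ", het=False):
    """Build one fixed-column ATOM/HETATM line for hand-made test inputs."""
    record = "HETATM" if het else "ATOM  "
    element = element if element is not None else name[0]
    padded = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record}{serial:>5d} {padded:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture(scope="session")
def reference_potential():
    return load_reference_potential()


@pytest.fixture(scope="session")
def benchmark_table():
    return load_benchmark_table()
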