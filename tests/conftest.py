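import random

import pytest

from cdemdr.clinpharm import clinpharm_table2_extract, load_clinpharm_fixture
from cdemdr.model import (
    ClinicalDomain,
    DataElement,
    DomainVariable,
    ObjectClass,
    PermissibleValue,
    PropertyDef,
    Registry,
    ValueDomain,
    build_registry,
)


@pytest.fixture(scope="session")
def clinpharm():
    return load_clinpharm_fixture()


@pytest.fixture(scope="session")
def table2_extract():
    return clinpharm_table2_extract()


def random_elements(rng: random.Random, n: int) -> list[DataElement]:
    """Random well-formed data elements over small shared component pools."""
    ocs = [
        ObjectClass(
            name=f"Object Class {i}",
            public_id=f"OC{i}" if rng.random() < 0.5 else None,
        )
        for i in range(rng.randint(1, 5))
    ]
    props = [PropertyDef(name=f"Property {i}") for i in range(rng.randint(1, 6))]
    vds = [
        ValueDomain(
            name=f"Value Domain {i}",
            datatype="string",
            permissible_values=(
                (PermissibleValue("Y"), PermissibleValue("N"))
                if rng.random() < 0.5
                else ()
            ),
        )
        for i in range(rng.randint(1, 4))
    ]
    return [
        DataElement(
            public_id=str(1000 + i),
            version="1.0",
            long_name=f"Element {i}",
            object_class=rng.choice(ocs),
            property=rng.choice(props),
            value_domain=rng.choice(vds),
        )
        for i in range(n)
    ]


def random_registry_and_domain(
    seed: int, n_elements: int = 12, n_vars: int | None = None
) -> tuple[Registry, ClinicalDomain]:
    """A random registry plus a domain asserting a random subset of it."""
    rng = random.Random(seed)
    elements = random_elements(rng, n_elements)
    registry = build_registry(elements)
    if n_vars is None:
        n_vars = rng.randint(0, n_elements)
    chosen = rng.sample(elements, min(n_vars, len(elements)))
    domain = ClinicalDomain(
        name="random domain",
        variables=tuple(
            DomainVariable(
                variable_name=f"Variable {i}", cde_ref=de.public_id, position=i
            )
            for i, de in enumerate(chosen)
        ),
    )
    return registry, domain
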