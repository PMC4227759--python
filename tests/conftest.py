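import pytest
from hypothesis import HealthCheck, settings

from paperclip.assembly import AssemblyElement, plan_assembly
from paperclip.fixtures import generate_fixture_parts, toy_parts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_library():
    return toy_parts()


@pytest.fixture(scope="session")
def six_part_library():
    """Six random parts, fixed seed — the smallest library exercising reuse."""
    return generate_fixture_parts(6, (200, 400), seed=1)


@pytest.fixture(scope="session")
def backbone_part():
    return generate_fixture_parts(1, (600, 600), seed=42, prefix="bb")["bb1"]


@pytest.fixture(scope="session")
def three_element_plan(backbone_part, toy_library):
    library = {"bb1": backbone_part, **toy_library}
    order = [
        AssemblyElement("bb1"),
        AssemblyElement("TOY1"),
        AssemblyElement("TOY2"),
    ]
    return plan_assembly(library, order)
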