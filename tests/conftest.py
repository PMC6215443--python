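import numpy as np
import pytest

from trajpose.bone_stress import BONES, CrossSection
from trajpose.musculoskeletal import ModelSpec, MuscleSpec, Posture, static_optimization
from trajpose.synthetic_limb import (
    FabricScenario,
    build_species_template,
    default_rois,
    generate_fabric_field,
)


def toy_template(
    muscles,
    femur=1.0,
    tibiotarsus=1.0,
    tarsometatarsus=0.5,
    pes=0.4,
    limb_mass=1e-9,
    total_mass=100.0,
):
    """Minimal hand-built template for closed-form toy problems."""
    from trajpose.synthetic_limb import SpeciesTemplate

    lengths = {
        "femur": femur,
        "tibiotarsus": tibiotarsus,
        "tarsometatarsus": tarsometatarsus,
        "pes": pes,
    }
    masses = {s: limb_mass / 4 for s in lengths}
    sections = {
        b: CrossSection(a_ap=0.05 * lengths[b], a_ml=0.05 * lengths[b]) for b in BONES
    }
    return SpeciesTemplate(
        name="toy",
        total_body_mass=total_mass,
        right_hindlimb_mass=limb_mass,
        pelvis_segment_mass=total_mass - limb_mass,
        segment_lengths=lengths,
        segment_masses=masses,
        pelvis_com_offset_anterior=0.1,
        cross_sections=sections,
        epiphysis_radii={b: 0.09 * lengths[b] for b in BONES},
        muscle_roster=tuple(muscles),
    )


@pytest.fixture(scope="session")
def troodontid_template():
    return build_species_template("troodontid-scale")


@pytest.fixture(scope="session")
def troodontid_model(troodontid_template):
    return ModelSpec.from_template(troodontid_template)


@pytest.fixture(scope="session")
def default_posture():
    return Posture()


@pytest.fixture(scope="session")
def troodontid_solution(troodontid_model, default_posture):
    return static_optimization(troodontid_model, default_posture)


@pytest.fixture(scope="session")
def search_rois(troodontid_template):
    # the tensile-mode ROI uses a degenerate orthogonal-complement surrogate
    # and is excluded from the smooth search scoring set
    return [r for r in default_rois(troodontid_template) if r.mode == "compressive"]


@pytest.fixture(scope="session")
def zero_noise_fabric(troodontid_template, default_posture):
    scenario = FabricScenario(
        true_posture=default_posture, axial_concentration=float("inf"), rng_seed=1
    )
    return generate_fabric_field(troodontid_template, scenario)
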