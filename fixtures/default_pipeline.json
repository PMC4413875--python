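{
  "_doc": "Default desk-scale study conditions: a 2D crystal of a large membrane rotary ATPase imaged by single-axis cryo-ET. All lengths in Angstrom, angles in degrees.",
  "phantom": {
    "_doc": "Geometric complex model: 100 A spherical catalytic head 150 A above the membrane midplane, central and peripheral stalks, membrane-embedded rotor ring; soft (erf) density edges.",
    "head_diameter": 100.0,
    "head_height": 150.0,
    "central_stalk_radius": 10.0,
    "central_stalk_length": 80.0,
    "peripheral_stalk_radius": 16.0,
    "peripheral_stalk_offset": 40.0,
    "cring_radius_outer": 22.0,
    "cring_radius_inner": 12.0,
    "membrane_thickness": 40.0,
    "protein_density": 1.0,
    "lipid_density": 0.5,
    "edge_sigma": 8.0,
    "center_height": 90.0
  },
  "crystal": {
    "_doc": "Oblique 2D lattice with two up-face and two down-face monomers per cell; long axes inclined 16 deg from the crystal normal, pair azimuths 97.93 deg apart (giving a 24.0 deg intra-pair axis angle), cross-membrane partners related by a 90 deg in-plane rotation, zigzag bilayer with a 43 deg kink at each particle row.",
    "a": 179.1,
    "b": 171.4,
    "gamma": 94.9,
    "inclination_theta": 16.0,
    "pair_azimuth_delta": 97.93,
    "interface_rotation": 90.0,
    "kink_kappa": 43.0,
    "base_azimuth": 0.0,
    "cross_face_offset": 30.0,
    "jitter_sigma_xy": 2.0,
    "jitter_sigma_angle": 1.0,
    "seed": 0
  },
  "tomogram": {
    "_doc": "Reconstruction grid: 96^3 voxels at 6.66 A/voxel (~3.5 x 3.5 unit cells in plane).",
    "box": [96, 96, 96],
    "voxel_size": 6.66
  },
  "tilt": {
    "_doc": "Single-axis tilt series, +/-60 deg in 1.5 deg steps (81 images), white Gaussian projection noise.",
    "min": -60.0,
    "max": 60.0,
    "step": 1.5,
    "noise_sigma": 8.0
  },
  "averaging": {
    "_doc": "Gold-standard refinement: 48-voxel boxes, rotations limited to 45 deg off-axis with free azimuth/spin, shifts to 12 voxels, 60->40->30 A coarse-to-fine schedule.",
    "box": 48,
    "constraints": {"max_xy_rot": 45.0, "max_shift": 12.0},
    "schedule": [
      {"binning": 2, "resolution_limit": 60.0, "angular_step": 12.0, "iterations": 2, "search": "global", "shift_limit": 3.0},
      {"binning": 2, "resolution_limit": 40.0, "angular_step": 10.0, "iterations": 2, "search": "psi", "shift_limit": 6.0},
      {"binning": 1, "resolution_limit": 30.0, "angular_step": 3.0, "iterations": 2, "search": "local"}
    ]
  },
  "validation": {
    "_doc": "FSC 0.5 criterion; phase randomization beyond 40 A; Fermi display filter at 18 A with temperature 0.002 per pixel.",
    "fsc_threshold": 0.5,
    "randomization_cutoff": 40.0,
    "fermi_cutoff": 18.0,
    "fermi_temperature": 0.002
  },
  "geometry": {
    "_doc": "Pair/interface assignment cutoffs on mid-membrane anchor points (A).",
    "same_face_cutoff": 140.0,
    "cross_face_cutoff": 70.0
  },
  "crystallography": {
    "_doc": "z-slice span of 426.2 A (64 layers at 6.66 A) and a 30 A resolution limit for structure factors and maps.",
    "slab_span": 426.2,
    "resolution_limit": 30.0
  },
  "seed": 7
}
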