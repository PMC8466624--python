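{
  "comment": "Simplified Ramachandran region polygons used to classify (phi, psi) pairs into favored / allowed / unfavorable. Vertices are [phi, psi] in degrees on the square (-180, 180]. A point is 'favored' if inside any favored polygon, else 'allowed' if inside any allowed polygon, else 'unfavorable'. The favored set covers the broad beta/PPII basin (split across the psi wrap) and the right-handed alpha basin; the allowed set is the generously-allowed negative-phi half-plane plus the left-handed alpha basin.",
  "favored": [
    {"name": "beta_upper", "vertices": [[-180, 85], [-45, 85], [-45, 180], [-180, 180]]},
    {"name": "beta_wrap", "vertices": [[-180, -180], [-45, -180], [-45, -150], [-180, -150]]},
    {"name": "alpha_right", "vertices": [[-160, -70], [-20, -70], [-20, 10], [-160, 10]]}
  ],
  "allowed": [
    {"name": "negative_phi", "vertices": [[-180, -180], [0, -180], [0, 180], [-180, 180]]},
    {"name": "alpha_left", "vertices": [[20, -20], [100, -20], [100, 90], [20, 90]]}
  ]
}
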