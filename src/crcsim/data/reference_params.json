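{
 "Ce": 0.059919,
 "Cy": 0.019328,
 "D": 1.0,
 "E0": 0.5,
 "G": 1.0,
 "S": 1.0,
 "U": 1.0,
 "d1": 0.58435,
 "d2": 0.37855,
 "d3": 0.00685,
 "m_e": 0.082263,
 "m_p": 6.4,
 "m_u": 0.77,
 "m_w": 0.77,
 "m_x": 0.514582,
 "m_y": 0.028114,
 "m_z": 0.77,
 "p0": 0.0,
 "provenance": {
  "method": "multi-start derivative-free calibration to the wild-type curve anchors (x0 0.8 AU, peak 2.95 AU near 10 h, sharp decline from 15 h lasting 3 h), with out-of-sample validation of the delay, dosage and knockout claims",
  "seed": 0
 },
 "q": 197.391547,
 "sigmoid_asc_auto.a": 3.766713,
 "sigmoid_asc_auto.b": 0.834651,
 "sigmoid_asc_auto.n": 2.0,
 "sigmoid_asc_chn.a": 0.73906,
 "sigmoid_asc_chn.b": 0.3,
 "sigmoid_asc_chn.n": 2.0,
 "sigmoid_asc_sens.a": 1.701322,
 "sigmoid_asc_sens.b": 0.3,
 "sigmoid_asc_sens.n": 2.0,
 "sigmoid_chn.a": 0.43267,
 "sigmoid_chn.b": 0.35,
 "sigmoid_chn.n": 2.0,
 "sigmoid_phyl.a": 0.5,
 "sigmoid_phyl.b": 1.241366,
 "sigmoid_phyl.n": 3.0,
 "sigmoid_scrt.a": 0.19558,
 "sigmoid_scrt.b": 0.5,
 "sigmoid_scrt.n": 2.0,
 "sigmoid_sens.a": 0.224273,
 "sigmoid_sens.b": 0.602604,
 "sigmoid_sens.n": 2.0,
 "tau_reference": 14.8883,
 "u0": 0.0,
 "version": "crcsim-parameters-1",
 "w0": 0.0,
 "x0": 0.8,
 "y0": 0.5,
 "z0": 0.0
}
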