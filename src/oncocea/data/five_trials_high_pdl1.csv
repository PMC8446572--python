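trial,arm_a,arm_b,endpoint,effect,ci_low,ci_high,events_a,n_a,events_b,n_b
KEYNOTE-024,pembrolizumab,chemotherapy,OS,0.60,0.41,0.89,,,,
KEYNOTE-024,pembrolizumab,chemotherapy,PFS,0.50,0.37,0.68,,,,
KEYNOTE-024,pembrolizumab,chemotherapy,SAE,,,,41,154,80,150
KEYNOTE-042,pembrolizumab,chemotherapy,OS,0.69,0.56,0.85,,,,
KEYNOTE-042,pembrolizumab,chemotherapy,PFS,0.81,0.67,0.99,,,,
KEYNOTE-042,pembrolizumab,chemotherapy,SAE,,,,113,636,252,615
CheckMate-026,nivolumab,chemotherapy,OS,0.90,0.63,1.29,,,,
CheckMate-026,nivolumab,chemotherapy,PFS,1.07,0.77,1.49,,,,
CheckMate-026,nivolumab,chemotherapy,SAE,,,,47,267,133,263
IMpower110,atezolizumab,chemotherapy,OS,0.59,0.40,0.89,,,,
IMpower110,atezolizumab,chemotherapy,PFS,0.63,0.45,0.88,,,,
IMpower110,atezolizumab,chemotherapy,SAE,,,,86,286,138,263
MYSTIC,durvalumab,chemotherapy,OS,0.76,0.564,1.019,,,,
MYSTIC,durvalumab,chemotherapy,PFS,0.87,0.59,1.29,,,,
MYSTIC,durvalumab,chemotherapy,SAE,,,,55,369,112,332
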