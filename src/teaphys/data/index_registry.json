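{
  "version": "1.0",
  "notes": "Color indices (CI) are evaluated on RGB digital numbers normalized to [0,1] (symbols R,G,B) and on chromatic coordinates r=R/(R+G+B) etc. Multispectral indices (MI) use reflectances: B=blue, G=green, R=red, RE=red_edge, N=nir. EVI constants G=2.5, C1=6, C2=7.5, L=1.",
  "indices": [
    {"name": "r_chrom", "family": "CI", "bands": ["R", "G", "B"], "formula": "r"},
    {"name": "g_chrom", "family": "CI", "bands": ["R", "G", "B"], "formula": "g"},
    {"name": "b_chrom", "family": "CI", "bands": ["R", "G", "B"], "formula": "b"},
    {"name": "ExG", "family": "CI", "bands": ["R", "G", "B"], "formula": "2*g - r - b"},
    {"name": "ExR", "family": "CI", "bands": ["R", "G", "B"], "formula": "1.4*r - g"},
    {"name": "ExB", "family": "CI", "bands": ["R", "G", "B"], "formula": "1.4*b - g"},
    {"name": "ExGR", "family": "CI", "bands": ["R", "G", "B"], "formula": "(2*g - r - b) - (1.4*r - g)"},
    {"name": "NGRDI", "family": "CI", "bands": ["R", "G", "B"], "formula": "(G - R)/(G + R)"},
    {"name": "NGBDI", "family": "CI", "bands": ["R", "G", "B"], "formula": "(G - B)/(G + B)"},
    {"name": "RGRI", "family": "CI", "bands": ["R", "G", "B"], "formula": "R/G"},
    {"name": "GLI", "family": "CI", "bands": ["R", "G", "B"], "formula": "(2*G - R - B)/(2*G + R + B)"},
    {"name": "MGRVI", "family": "CI", "bands": ["R", "G", "B"], "formula": "(G**2 - R**2)/(G**2 + R**2)"},
    {"name": "RGBVI", "family": "CI", "bands": ["R", "G", "B"], "formula": "(G**2 - R*B)/(G**2 + R*B)"},
    {"name": "VARI", "family": "CI", "bands": ["R", "G", "B"], "formula": "(G - R)/(G + R - B)"},
    {"name": "CIVE", "family": "CI", "bands": ["R", "G", "B"], "formula": "0.441*r - 0.811*g + 0.385*b + 18.78745"},
    {"name": "VEG", "family": "CI", "bands": ["R", "G", "B"], "formula": "g/(r**0.667 * b**0.333)"},
    {"name": "WI", "family": "CI", "bands": ["R", "G", "B"], "formula": "(g - b)/(r - g)"},
    {"name": "IKAW", "family": "CI", "bands": ["R", "G", "B"], "formula": "(R - B)/(R + B)"},
    {"name": "INT", "family": "CI", "bands": ["R", "G", "B"], "formula": "(R + G + B)/3"},
    {"name": "NDVI", "family": "MI", "bands": ["nir", "red"], "formula": "(N - R)/(N + R)"},
    {"name": "GNDVI", "family": "MI", "bands": ["nir", "green"], "formula": "(N - G)/(N + G)"},
    {"name": "BNDVI", "family": "MI", "bands": ["nir", "blue"], "formula": "(N - B)/(N + B)"},
    {"name": "NDRE", "family": "MI", "bands": ["nir", "red_edge"], "formula": "(N - RE)/(N + RE)"},
    {"name": "RVI", "family": "MI", "bands": ["nir", "red"], "formula": "N/R"},
    {"name": "GRVI", "family": "MI", "bands": ["nir", "green"], "formula": "N/G"},
    {"name": "RERVI", "family": "MI", "bands": ["nir", "red_edge"], "formula": "N/RE"},
    {"name": "DVI", "family": "MI", "bands": ["nir", "red"], "formula": "N - R"},
    {"name": "GDVI", "family": "MI", "bands": ["nir", "green"], "formula": "N - G"},
    {"name": "RDVI", "family": "MI", "bands": ["nir", "red"], "formula": "(N - R)/sqrt(N + R)"},
    {"name": "EVI", "family": "MI", "bands": ["nir", "red", "blue"], "formula": "2.5*(N - R)/(N + 6*R - 7.5*B + 1)"},
    {"name": "EVI2", "family": "MI", "bands": ["nir", "red"], "formula": "2.5*(N - R)/(N + 2.4*R + 1)"},
    {"name": "SAVI", "family": "MI", "bands": ["nir", "red"], "formula": "1.5*(N - R)/(N + R + 0.5)"},
    {"name": "OSAVI", "family": "MI", "bands": ["nir", "red"], "formula": "1.16*(N - R)/(N + R + 0.16)"},
    {"name": "MSAVI", "family": "MI", "bands": ["nir", "red"], "formula": "(2*N + 1 - sqrt((2*N + 1)**2 - 8*(N - R)))/2"},
    {"name": "GSAVI", "family": "MI", "bands": ["nir", "green"], "formula": "1.5*(N - G)/(N + G + 0.5)"},
    {"name": "GOSAVI", "family": "MI", "bands": ["nir", "green"], "formula": "(N - G)/(N + G + 0.16)"},
    {"name": "MSR", "family": "MI", "bands": ["nir", "red"], "formula": "(N/R - 1)/sqrt(N/R + 1)"},
    {"name": "MSRre", "family": "MI", "bands": ["nir", "red_edge"], "formula": "(N/RE - 1)/sqrt(N/RE + 1)"},
    {"name": "NLI", "family": "MI", "bands": ["nir", "red"], "formula": "(N**2 - R)/(N**2 + R)"},
    {"name": "MNLI", "family": "MI", "bands": ["nir", "red"], "formula": "1.5*(N**2 - R)/(N**2 + R + 0.5)"},
    {"name": "TVI", "family": "MI", "bands": ["nir", "green", "red"], "formula": "0.5*(120*(N - G) - 200*(R - G))"},
    {"name": "MTVI1", "family": "MI", "bands": ["nir", "green", "red"], "formula": "1.2*(1.2*(N - G) - 2.5*(R - G))"},
    {"name": "MTVI2", "family": "MI", "bands": ["nir", "green", "red"], "formula": "1.5*(1.2*(N - G) - 2.5*(R - G))/sqrt((2*N + 1)**2 - (6*N - 5*sqrt(R)) - 0.5)"},
    {"name": "MCARI", "family": "MI", "bands": ["red_edge", "red", "green"], "formula": "((RE - R) - 0.2*(RE - G))*(RE/R)"},
    {"name": "TCARI", "family": "MI", "bands": ["red_edge", "red", "green"], "formula": "3*((RE - R) - 0.2*(RE - G)*(RE/R))"},
    {"name": "MCARI2", "family": "MI", "bands": ["nir", "red", "green"], "formula": "1.5*(2.5*(N - R) - 1.3*(N - G))/sqrt((2*N + 1)**2 - (6*N - 5*sqrt(R)) - 0.5)"},
    {"name": "CIgreen", "family": "MI", "bands": ["nir", "green"], "formula": "N/G - 1"},
    {"name": "CIrededge", "family": "MI", "bands": ["nir", "red_edge"], "formula": "N/RE - 1"},
    {"name": "CVI", "family": "MI", "bands": ["nir", "red", "green"], "formula": "N*R/G**2"},
    {"name": "ARVI", "family": "MI", "bands": ["nir", "red", "blue"], "formula": "(N - (2*R - B))/(N + (2*R - B))"},
    {"name": "GARI", "family": "MI", "bands": ["nir", "green", "blue", "red"], "formula": "(N - (G - (B - R)))/(N + (G - (B - R)))"},
    {"name": "SIPI", "family": "MI", "bands": ["nir", "blue", "red"], "formula": "(N - B)/(N - R)"},
    {"name": "PSRI", "family": "MI", "bands": ["red", "green", "red_edge"], "formula": "(R - G)/RE"},
    {"name": "WDRVI", "family": "MI", "bands": ["nir", "red"], "formula": "(0.2*N - R)/(0.2*N + R)"},
    {"name": "LCI", "family": "MI", "bands": ["nir", "red_edge", "red"], "formula": "(N - RE)/(N + R)"},
    {"name": "MTCI", "family": "MI", "bands": ["nir", "red_edge", "red"], "formula": "(N - RE)/(RE - R)"},
    {"name": "IPVI", "family": "MI", "bands": ["nir", "red"], "formula": "N/(N + R)"},
    {"name": "GEMI", "family": "MI", "bands": ["nir", "red"], "formula": "((2*(N**2 - R**2) + 1.5*N + 0.5*R)/(N + R + 0.5))*(1 - 0.25*((2*(N**2 - R**2) + 1.5*N + 0.5*R)/(N + R + 0.5))) - (R - 0.125)/(1 - R)"},
    {"name": "TCARI_OSAVI", "family": "MI", "bands": ["red_edge", "red", "green", "nir"], "formula": "(3*((RE - R) - 0.2*(RE - G)*(RE/R)))/(1.16*(N - R)/(N + R + 0.16))"},
    {"name": "NDGI", "family": "MI", "bands": ["green", "red"], "formula": "(G - R)/(G + R)"},
    {"name": "REGNDVI", "family": "MI", "bands": ["red_edge", "green"], "formula": "(RE - G)/(RE + G)"},
    {"name": "RERI", "family": "MI", "bands": ["red_edge", "red"], "formula": "RE/R"},
    {"name": "TNDVI", "family": "MI", "bands": ["nir", "red"], "formula": "sqrt((N - R)/(N + R) + 0.5)"},
    {"name": "GBNDVI", "family": "MI", "bands": ["nir", "green", "blue"], "formula": "(N - (G + B))/(N + (G + B))"},
    {"name": "RBNDVI", "family": "MI", "bands": ["nir", "red", "blue"], "formula": "(N - (R + B))/(N + (R + B))"},
    {"name": "PNDVI", "family": "MI", "bands": ["nir", "green", "red", "blue"], "formula": "(N - (G + R + B))/(N + (G + R + B))"},
    {"name": "NNIR", "family": "MI", "bands": ["nir", "red", "green"], "formula": "N/(N + R + G)"},
    {"name": "NGI", "family": "MI", "bands": ["nir", "red", "green"], "formula": "G/(N + R + G)"},
    {"name": "NRI", "family": "MI", "bands": ["nir", "red", "green"], "formula": "R/(N + R + G)"}
  ]
}
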