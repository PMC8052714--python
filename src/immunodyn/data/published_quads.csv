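section,modulator,source,target,lsv,occ_cancer_12A,occ_healthy_10
bilinear,IP-10,CD3+,CD3+,CD3+,100.00,100.00
bilinear,IP-10,CD3+,IL-8,IL-8,93.75,89.58
bilinear,IP-10,CD3+,IL-8,EOTAXIN,35.42,2.08
bilinear,IP-10,CD3+,IL-8,IP-10,29.17,2.08
bilinear,IP-10,CD3+,IL-8,MCP-1,29.17,6.25
bilinear,IP-10,CD3+,IL-8,VEGF,25.00,6.25
bilinear,IP-10,CD3+,IL-8,TGFA,20.83,16.67
bilinear,IP-10,CD3+,IL-8,IL-1A,20.83,8.33
bilinear,IP-10,CD3+,IL-8,EGF,18.75,4.17
bilinear,IP-10,CD3+,IL-8,IL-12P40,14.58,2.08
bilinear,IP-10,CD3+,IL-8,FGF-2,14.58,2.08
bilinear,IP-10,CD3+,IL-8,FRACTALKINE,14.58,4.17
bilinear,IP-10,CD3+,IL-8,G-CSF,12.50,0.00
bilinear,IP-10,CD3+,IL-8,IL-12P70,12.50,0.00
bilinear,IP-10,CD3+,IL-8,IL-1RA,12.50,4.17
bilinear,IP-10,CD3+,IL-8,IL-3,12.50,2.08
bilinear,IP-10,CD3+,IL-8,MCP-3,12.50,2.08
bilinear,IP-10,CD3+,IL-8,TNFB,12.50,2.08
bilinear,IP-10,CD3+,IL-8,IFN-G,10.42,0.00
bilinear,IP-10,CD3+,IL-8,IL-2,10.42,0.00
bilinear,IP-10,CD3+,IL-8,MIP-1A,10.42,0.00
bilinear,IP-10,CD3+,IL-8,GM-CSF,8.33,0.00
bilinear,IP-10,CD3+,IL-8,IFN-2A,8.33,2.08
bilinear,IP-10,CD3+,IL-8,IL-10,6.25,0.00
bilinear,IP-10,CD3+,IL-8,IL-13,6.25,4.17
bilinear,IP-10,CD3+,IL-8,IL-17A,6.25,0.00
bilinear,IP-10,CD3+,IL-8,IL-1B,6.25,4.17
bilinear,IP-10,CD3+,IL-8,IL-4,6.25,4.17
bilinear,IP-10,CD3+,IL-8,IL-9,6.25,4.17
bilinear,IP-10,CD3+,IL-8,MIP-1B,6.25,0.00
bilinear,IP-10,CD3+,IL-8,TNFA,6.25,2.08
bilinear,IP-10,CD3+,IL-8,FLT-3L,4.17,0.00
bilinear,IP-10,CD3+,IL-8,IL-7,4.17,2.08
bilinear,IP-10,CD3+,IL-8,IL-15,2.08,2.08
bilinear,IP-10,CD3+,IL-8,IL-6,2.08,4.17
bilinear,IP-10,CD3+,IL-8,IL-5,0.00,0.00
linear,n.a.,IL-8,CD3/CD69+,CD3/CD69+,18.75,0.00
linear,n.a.,IL-8,CD11c/CD86+,CD11c/CD86+,10.42,0.00
linear,n.a.,IL-8,CD11c/HLA-DR+,CD11c/HLA-DR+,10.42,0.00
linear,n.a.,IL-8,CD11c+,CD11c+,8.33,0.00
linear,n.a.,IL-8,CD4/CD294+,CD4/CD294+,6.25,0.00
linear,n.a.,IL-8,CD4/TIM3+,CD4/TIM3+,6.25,0.00
linear,n.a.,IL-8,CD56+,CD56+,2.08,0.00
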