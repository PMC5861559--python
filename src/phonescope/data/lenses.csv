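Lens,Supplier,Cost ($),Material,NA,Focal length (mm),Working distance (mm),Diameter (mm),Clear aperture (mm)
C170TME-A,Thorlabs,60,C0550 Glass,0.3,6.16,4.38,4.72,3.7
CAW110,Thorlabs,6,COC,0.19,10.92,9.33,6.28,3.4
CAY033,Thorlabs,6,Acrylic,0.4,3.3,2.0,7.4,2.7
CAY046,Thorlabs,6,Acrylic,0.4,4.6,3.0,7.4,3.7
Budget,Unknown,<1,Unknown,0.19,14,12.4,6.95,5.2
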