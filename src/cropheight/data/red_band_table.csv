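date,rice_color,condition,referenced_cm,estimated_cm,relative_error_pct
2012-07-01,green,normal,77.0,77.0,0.00
2012-07-02,green,normal,77.0,77.0,0.00
2012-07-03,green,normal,77.0,80.9,5.04
2012-07-04,green,normal,78.0,77.0,1.28
2012-07-05,green,normal,78.0,75.7,2.94
2012-07-06,green,normal,79.0,75.7,4.17
2012-07-07,green,normal,80.0,80.9,1.10
2012-07-08,green,normal,81.0,78.3,3.34
2012-07-09,green,normal,81.0,75.7,6.54
2012-07-10,green,normal,82.0,77.0,6.10
2012-07-11,green,darkness,84.0,176.6,110.29
2012-07-12,green,normal,85.0,82.2,3.32
2012-07-13,green,normal,87.0,84.7,2.57
2012-07-14,green,normal,85.0,82.2,3.32
2012-07-15,green,normal,87.0,82.2,5.54
2012-07-16,green,normal,88.0,82.2,6.62
2012-07-17,green,normal,89.0,91.2,2.51
2012-07-18,green,darkness,99.0,176.6,78.43
2012-07-19,green,drizzle,108.0,174.0,61.17
2012-07-20,golden,normal,116.0,111.9,3.50
2012-07-21,golden,normal,119.0,115.8,2.67
2012-07-22,golden,normal,119.0,133.9,12.56
2012-07-23,golden,normal,117.0,118.4,1.21
2012-07-24,golden,darkness,117.0,174.1,48.77
2012-07-25,golden,rainfall,117.0,188.3,60.94
2012-07-26,golden,normal,119.0,119.7,0.59
2012-07-27,golden,darkness,117.0,171.5,46.56
2012-07-28,golden,normal,115.0,143.0,24.35
2012-07-29,golden,normal,115.0,117.1,1.84
2012-07-30,golden,darkness,111.0,157.2,41.65
2012-07-31,golden,normal,112.0,117.1,4.57
2012-08-01,golden,normal,112.0,155.9,39.23
2012-08-02,golden,darkness,110.0,159.8,45.29
2012-08-03,golden,normal,109.0,172.8,58.50
2012-08-04,golden,brightness,108.0,111.9,3.65
2012-08-05,golden,brightness,108.0,114.5,6.05
2012-08-06,golden,darkness,108.0,158.5,46.79
2012-08-07,golden,normal,111.0,152.1,36.99
2012-08-08,golden,darkness,110.0,161.1,46.47
2012-08-09,golden,darkness,110.0,161.1,46.47
2012-08-10,golden,normal,109.0,150.8,38.32
2012-08-11,golden,normal,108.0,145.6,34.80
2012-08-12,golden,normal,110.0,145.6,32.35
2012-08-13,golden,normal,107.0,155.9,45.74
2012-08-14,golden,normal,105.0,158.5,50.98
2012-08-15,golden,normal,106.0,149.5,41.00
2012-08-16,golden,brightness,106.0,106.7,0.72
2012-08-17,golden,normal,100.0,166.3,66.29
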